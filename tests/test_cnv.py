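"""Reciprocal overlap, CNV filter cascades, cohort frequency, gene-set burden."""

import numpy as np
import pandas as pd
import pytest

from isocohort.datamodel import make_cnv_table
from isocohort import cnv as icnv


def cnv_row(sample="S1", chrom="1", start=1, end=100_000, type_="deletion",
            source="wes", conf=95.0, targets=8, segdup=0.0):
    return dict(sample_id=sample, chrom=chrom, start=start, end=end, type=type_,
                source=source, confidence=conf, n_probes_or_targets=targets,
                segdup_overlap_fraction=segdup)


# ---------------------------------------------------------------------------
# Reciprocal overlap

def test_reciprocal_overlap_identical():
    assert icnv.reciprocal_overlap((1, 100), (1, 100)) == 1.0


def test_reciprocal_overlap_half():
    assert icnv.reciprocal_overlap((1, 100), (51, 150)) == pytest.approx(0.5)


def test_reciprocal_overlap_disjoint_and_errors():
    assert icnv.reciprocal_overlap((1, 100), (200, 300)) == 0.0
    with pytest.raises(ValueError):
        icnv.reciprocal_overlap((10, 5), (1, 100))


def test_reciprocal_overlap_symmetric_and_monotone():
    rng = np.random.default_rng(0)
    for _ in range(50):
        a = sorted(rng.integers(1, 1000, size=2))
        b = sorted(rng.integers(1, 1000, size=2))
        a = (int(a[0]), int(a[1]) + 1)
        b = (int(b[0]), int(b[1]) + 1)
        f1 = icnv.reciprocal_overlap(a, b)
        assert f1 == icnv.reciprocal_overlap(b, a)
        assert 0.0 <= f1 <= 1.0
    # widening b's overlap with a never decreases the fraction of a covered
    assert icnv.reciprocal_overlap((1, 100), (41, 140)) > \
        icnv.reciprocal_overlap((1, 100), (61, 160))


# ---------------------------------------------------------------------------
# Filter cascades

def test_array_small_cnv_removed():
    t = make_cnv_table(pd.DataFrame([cnv_row(source="array", end=40_000, conf=50,
                                             targets=10)]))
    kept, report = icnv.filter_cnvs(t)
    assert report["array_min_size_keep"] == 1 and len(kept) == 0


def test_wes_few_targets_removed():
    t = make_cnv_table(pd.DataFrame([cnv_row(targets=4)]))
    kept, report = icnv.filter_cnvs(t)
    assert report["wes_targets"] == 1 and len(kept) == 0


def test_filter_fixture_with_known_fates():
    rows = [
        cnv_row("A", source="array", targets=2, conf=50),              # min probes
        cnv_row("B", source="array", end=900, conf=50, targets=5),     # detect size
        cnv_row("C", source="array", conf=10, targets=5),              # call score
        cnv_row("D", source="array", conf=20, targets=5),              # merge score
        cnv_row("E", source="array", end=30_000, conf=60, targets=5),  # keep size
        cnv_row("F", source="array", conf=60, targets=5, segdup=0.8),  # segdup
        cnv_row("G", source="array", conf=60, targets=5),              # passes
        cnv_row("H", source="wes", conf=80),                           # qsome
        cnv_row("I", source="wes", targets=3),                         # targets
        cnv_row("J", source="wes", segdup=0.6),                        # segdup
        cnv_row("K", source="wes"),                                    # passes
    ]
    t = make_cnv_table(pd.DataFrame(rows))
    kept, report = icnv.filter_cnvs(t)
    assert report == {"n_input": 11, "array_min_probes": 1, "array_min_size_detect": 1,
                      "array_min_call_score": 1, "array_min_merge_score": 1,
                      "array_min_size_keep": 1, "array_segdup": 1,
                      "wes_qsome": 1, "wes_targets": 1, "wes_segdup": 1, "n_kept": 2}
    assert sorted(kept["sample_id"]) == ["G", "K"]


def test_filter_cascade_idempotent():
    rows = [cnv_row("A"), cnv_row("B", source="array", conf=60, targets=5),
            cnv_row("C", conf=50)]
    t = make_cnv_table(pd.DataFrame(rows))
    once, _ = icnv.filter_cnvs(t)
    twice, report2 = icnv.filter_cnvs(once)
    pd.testing.assert_frame_equal(once, twice)
    assert report2["n_input"] == report2["n_kept"]


def test_segdup_union_fraction():
    segdups = pd.DataFrame(dict(chrom=["1", "1", "1"], start=[1, 40, 200],
                                end=[50, 100, 300]))
    # union of [1,50] and [40,100] covers [1,100] fully
    assert icnv.segdup_overlap_fraction(1, 100, segdups, "1") == 1.0
    assert icnv.segdup_overlap_fraction(101, 200, segdups, "1") == pytest.approx(0.01)
    assert icnv.segdup_overlap_fraction(1, 100, segdups, "2") == 0.0


def test_unknown_source_errors():
    t = make_cnv_table(pd.DataFrame([cnv_row()]))
    t2 = t.copy()
    t2.loc[0, "source"] = "nanopore"
    with pytest.raises(ValueError):
        icnv.filter_cnvs(t2)


# ---------------------------------------------------------------------------
# Cohort frequency vs all-pairs oracle

def frequency_oracle(table, reference_samples, overlap_min):
    freqs = []
    ref = [s for s in reference_samples]
    for _, r in table.iterrows():
        carriers = set()
        for sid in ref:
            for _, other in table[table["sample_id"] == sid].iterrows():
                if other["chrom"] != r["chrom"] or other["type"] != r["type"]:
                    continue
                if icnv.reciprocal_overlap((r["start"], r["end"]),
                                           (other["start"], other["end"])) >= overlap_min:
                    carriers.add(sid)
        freqs.append(len(carriers) / len(ref))
    return np.array(freqs)


def test_unique_call_frequency_self_only():
    t = make_cnv_table(pd.DataFrame([cnv_row("A")]))
    f = icnv.cnv_frequency(t, ["A", "B", "C", "D"], overlap_min=0.5)
    assert f[0] == pytest.approx(1 / 4)


def test_shared_by_all_frequency_one():
    rows = [cnv_row(s) for s in "ABCD"]
    t = make_cnv_table(pd.DataFrame(rows))
    f = icnv.cnv_frequency(t, list("ABCD"), overlap_min=0.5)
    np.testing.assert_allclose(f, 1.0)


def test_frequency_matches_all_pairs_oracle():
    rng = np.random.default_rng(3)
    rows = []
    for i in range(120):
        start = int(rng.integers(1, 500_000))
        rows.append(cnv_row(sample=f"S{rng.integers(0, 15)}",
                            chrom=str(rng.integers(1, 3)),
                            start=start, end=start + int(rng.integers(10_000, 200_000)),
                            type_="deletion" if rng.random() < 0.5 else "duplication"))
    t = make_cnv_table(pd.DataFrame(rows))
    ref = [f"S{i}" for i in range(12)]   # not all samples are reference
    got = icnv.cnv_frequency(t, ref, overlap_min=0.5)
    np.testing.assert_allclose(got, frequency_oracle(t, ref, 0.5))


# ---------------------------------------------------------------------------
# Gene-set burden

def make_genes():
    return pd.DataFrame(dict(gene=["G1", "G2", "G3"], chrom=["1", "1", "2"],
                             start=[1000, 100_000, 1000], end=[5000, 150_000, 5000]))


def test_zero_carriers_p_one():
    from isocohort.datamodel import GeneSetCollection
    t = make_cnv_table(pd.DataFrame([cnv_row("X", start=900_000, end=950_000)]))
    gs = GeneSetCollection({"S": frozenset({"G1"})})
    summary, res = icnv.cnv_geneset_burden(t, make_genes(), gs, ["A", "B"], ["C", "D"])
    assert res.p == 1.0


def test_burden_matches_fisher_oracle():
    from isocohort.datamodel import GeneSetCollection
    from isocohort.stats import fisher_exact
    # 3 case carriers of 5; 1 control carrier of 6 (calls hitting G1's exon)
    rows = [cnv_row(s, start=1000, end=6000) for s in ("A", "B", "C", "F")]
    t = make_cnv_table(pd.DataFrame(rows))
    gs = GeneSetCollection({"S": frozenset({"G1"})})
    cases, controls = ["A", "B", "C", "D", "E"], ["F", "G", "H", "I", "J", "K"]
    summary, res = icnv.cnv_geneset_burden(t, make_genes(), gs, cases, controls)
    assert res.p == fisher_exact([[3, 2], [1, 5]], alternative="greater").p
    assert summary.attrs["n_tests"] == 12


def test_deletions_and_duplications_tested_separately():
    from isocohort.datamodel import GeneSetCollection
    rows = [cnv_row("A", start=1000, end=6000, type_="deletion"),
            cnv_row("B", start=1000, end=6000, type_="duplication")]
    t = make_cnv_table(pd.DataFrame(rows))
    gs = GeneSetCollection({"S": frozenset({"G1"})})
    s_del, _ = icnv.cnv_geneset_burden(t, make_genes(), gs, ["A", "B"], ["C"],
                                       cnv_type="deletion")
    assert s_del["carriers"].tolist() == [1, 0]


def test_one_sibling_per_family():
    samples = pd.DataFrame(dict(
        sample_id=["c1", "s1", "s2", "k1"], family_id=["f1", "f1", "f1", "f2"],
        father_id="", mother_id="", sex="male",
        role=["case", "sibling", "sibling", "control"]))
    kept = icnv.keep_one_sibling_per_family(samples)
    assert sorted(kept["sample_id"]) == ["c1", "k1", "s1"]


def test_merge_array_callers_union():
    rows = [cnv_row("A", source="array", start=1000, end=100_000, conf=40, targets=4),
            cnv_row("A", source="array", start=30_000, end=120_000, conf=60, targets=6),
            cnv_row("A", source="array", start=500_000, end=600_000, conf=50, targets=5)]
    t = make_cnv_table(pd.DataFrame(rows))
    merged = icnv.merge_array_callers(t, icnv.CNVFilterParams())
    assert len(merged) == 2
    top = merged.sort_values("start").iloc[0]
    assert (top["start"], top["end"]) == (1000, 120_000)
    assert top["confidence"] == 60 and top["n_probes_or_targets"] == 10
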