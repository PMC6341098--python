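"""Variant classification, rarity filtering, de novo detection, load counting."""

import numpy as np
import pandas as pd
import pytest

from isocohort.datamodel import MISSING, AnnotatedVariantTable, GeneSetCollection
from isocohort import variants as iv


def make_table(records, gt, gq=None, dp=None, samples=None):
    gt = np.asarray(gt, dtype=np.int8)
    n_v, n_s = gt.shape
    samples = samples or [f"S{i}" for i in range(n_s)]
    gq = np.full(gt.shape, 99.0) if gq is None else np.asarray(gq, dtype=float)
    dp = np.full(gt.shape, 50, dtype=np.int32) if dp is None else np.asarray(dp, dtype=np.int32)
    df = pd.DataFrame(records)
    return AnnotatedVariantTable(df, samples, gt, gq, dp)


def var(chrom="1", pos=100, gene="G1", csq="missense", cadd=10.0, maf=0.001):
    return dict(chrom=chrom, pos=pos, ref="A", alt="T", gene=gene,
                consequence=csq, cadd=cadd, gnomad_maf=maf)


# ---------------------------------------------------------------------------
# Classification

@pytest.mark.parametrize("csq,cadd,expected", [
    ("stopgain", 12.0, "LGD"),
    ("splice_site", 5.0, "LGD"),
    ("frameshift", None, "LGD"),
    ("missense", 35.0, "MIS30"),
    ("missense", 30.0, "MIS30"),
    ("missense", 29.9, "OTHER"),
    ("synonymous", 45.0, "OTHER"),
    ("weird_label", 50.0, "OTHER"),
])
def test_classify_variant(csq, cadd, expected):
    assert iv.classify_variant(csq, cadd) == expected


# ---------------------------------------------------------------------------
# Rarity filter cascade

def test_gnomad_maf_filter():
    t = make_table([var(maf=0.02), var(pos=200, maf=0.005)], [[1, 0], [1, 0]])
    filt = iv.RarityFilter(max_gnomad_maf=0.01)
    kept, report = iv.apply_rarity_filter(t, filt, np.array([False, True]))
    assert report["gnomad_maf"] == 1
    assert kept.n_variants == 1
    assert kept.variants["pos"].tolist() == [200]


def test_internal_control_frequency_filter():
    # variant absent from gnomAD but at 25% allele frequency in controls
    n = 20
    gt = np.zeros((1, n), dtype=np.int8)
    gt[0, :10] = 1   # 10 het controls of 20 controls -> AF 0.25
    t = make_table([var(maf=np.nan)], gt)
    kept, report = iv.apply_rarity_filter(
        t, iv.RarityFilter(), np.ones(n, dtype=bool))
    assert report["internal_control_freq"] == 1
    assert kept.n_variants == 0


def test_low_gq_genotype_masked():
    gq = np.array([[25.0, 80.0]])
    t = make_table([var()], [[1, 1]], gq=gq)
    kept, report = iv.apply_rarity_filter(t, iv.RarityFilter(max_missing_fraction=1.0),
                                          np.array([False, False]))
    assert report["genotypes_masked"] == 1
    assert kept.gt[0, 0] == MISSING and kept.gt[0, 1] == 1


def test_missingness_site_filter():
    gt = np.array([[MISSING, MISSING, 1, 0, 0, 0, 0, 0, 0, 0]], dtype=np.int8)
    t = make_table([var()], gt)
    kept, report = iv.apply_rarity_filter(t, iv.RarityFilter(max_missing_fraction=0.10),
                                          np.zeros(10, dtype=bool))
    assert report["missingness"] == 1 and kept.n_variants == 0


def test_filter_is_idempotent(small_cohort):
    roles = small_cohort.samples.set_index("sample_id")["role"]
    ctrl = np.array([roles[s] == "control" for s in small_cohort.variants.samples])
    filt = iv.RarityFilter()
    once, _ = iv.apply_rarity_filter(small_cohort.variants, filt, ctrl)
    twice, report2 = iv.apply_rarity_filter(once, filt, ctrl)
    assert twice.n_variants == once.n_variants
    np.testing.assert_array_equal(once.gt, twice.gt)


# ---------------------------------------------------------------------------
# De novo

def trio_table(child_gt, father_gt, mother_gt):
    gt = np.array([[child_gt, father_gt, mother_gt]], dtype=np.int8)
    return make_table([var()], gt, samples=["child", "father", "mother"])


def test_denovo_basic():
    calls, _ = iv.detect_denovo(trio_table(1, 0, 0), [("child", "father", "mother")])
    assert len(calls) == 1 and calls[0].child_id == "child"


def test_inherited_not_denovo():
    calls, _ = iv.detect_denovo(trio_table(1, 1, 0), [("child", "father", "mother")])
    assert calls == []


def test_missing_parent_site_skipped():
    calls, info = iv.detect_denovo(trio_table(1, 0, MISSING),
                                   [("child", "father", "mother")])
    assert calls == [] and info["skipped_sites"] == 1


def test_homalt_denovo_configurable():
    t = trio_table(2, 0, 0)
    on, _ = iv.detect_denovo(t, [("child", "father", "mother")], count_hom_alt=True)
    off, _ = iv.detect_denovo(t, [("child", "father", "mother")], count_hom_alt=False)
    assert len(on) == 1 and off == []


def test_denovo_rate_arithmetic():
    samples = pd.DataFrame(dict(
        sample_id=["c1", "c2", "s1"], family_id=["f1", "f2", "f1"],
        sex="male", role=["case", "case", "sibling"]))
    calls = [iv.DenovoCall("c1", 0, "1", 100, "G1", 1),
             iv.DenovoCall("c1", 1, "1", 200, "G1", 1),
             iv.DenovoCall("c2", 0, "1", 100, "G1", 1)]
    rates = iv.denovo_rate(calls, samples)
    assert rates["case"] == pytest.approx(1.5)
    assert rates["sibling"] == pytest.approx(0.0)
    assert iv.denovo_rate([], samples)["case"] == 0.0


# ---------------------------------------------------------------------------
# Homozygous load

def test_load_zero_without_qualifying_sites():
    t = make_table([var(csq="synonymous")], [[2]])
    assert iv.homozygous_load(t, "S0").n_hom_deleterious == 0


def test_two_hom_sites_one_gene():
    t = make_table([var(csq="stopgain", pos=100), var(csq="missense", cadd=35, pos=200)],
                   [[2], [2]])
    prof = iv.homozygous_load(t, "S0")
    assert prof.n_hom_deleterious == 2
    assert prof.n_genes_hit == 1


def test_load_equals_recount_oracle(small_cohort):
    roles = small_cohort.samples.set_index("sample_id")["role"]
    ctrl = np.array([roles[s] == "control" for s in small_cohort.variants.samples])
    filtered, _ = iv.apply_rarity_filter(small_cohort.variants, iv.RarityFilter(), ctrl)
    for s in filtered.samples[:40]:
        prof = iv.homozygous_load(filtered, s)
        # independent recount: pure-python loop over records
        i = filtered.samples.index(s)
        n = 0
        genes = set()
        for j in range(filtered.n_variants):
            rec = filtered.variants.iloc[j]
            cls = ("LGD" if rec["consequence"] in ("stopgain", "splice_site", "frameshift")
                   else "MIS30" if rec["consequence"] == "missense" and rec["cadd"] >= 30
                   else "OTHER")
            if cls != "OTHER" and filtered.gt[j, i] == 2:
                n += 1
                genes.add(rec["gene"].upper())
        assert prof.n_hom_deleterious == n
        assert prof.genes_hit == frozenset(genes)


# ---------------------------------------------------------------------------
# Gene-set hit test

def test_identical_groups_p_one():
    gs = GeneSetCollection({"SFARI": frozenset({"G1"})})
    profs = [iv.LoadProfile(f"S{i}", 1, frozenset({"G1"})) for i in range(5)]
    _, res = iv.gene_set_hit_test(profs, list(profs), gs)
    assert res.p == 1.0


def test_extreme_enrichment_minimal_p():
    import math
    gs = GeneSetCollection({"SFARI": frozenset({"G1"})})
    cases = [iv.LoadProfile(f"C{i}", 1, frozenset({"G1"})) for i in range(5)]
    controls = [iv.LoadProfile(f"K{i}", 0, frozenset()) for i in range(5)]
    _, res = iv.gene_set_hit_test(cases, controls, gs)
    # minimal attainable one-sided p for margins (5 carriers among 10, groups 5/5)
    assert res.p == pytest.approx(1 / math.comb(10, 5))


def test_hit_test_matches_fisher_oracle():
    from isocohort.stats import fisher_exact
    gs = GeneSetCollection({"S": frozenset({"A"})})
    cases = [iv.LoadProfile(f"C{i}", 1, frozenset({"A"} if i < 3 else ())) for i in range(8)]
    controls = [iv.LoadProfile(f"K{i}", 1, frozenset({"A"} if i < 1 else ())) for i in range(10)]
    summary, res = iv.gene_set_hit_test(cases, controls, gs)
    assert res.p == fisher_exact([[3, 5], [1, 9]], alternative="greater").p
    assert summary["carriers"].tolist() == [3, 1]
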