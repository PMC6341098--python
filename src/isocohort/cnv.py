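"""CNV filtering, cohort frequency by reciprocal overlap, and gene-set burden.

Two platform-specific QC cascades are applied in a fixed, reported order:
array calls (probe count, size, detection and merge confidence scores,
segmental-duplication overlap) and whole-exome calls (QSOME score, target
count, segdup overlap).  Cohort frequency of a call is the fraction of
reference samples carrying a same-type call that matches it under the
reciprocal-overlap rule; calls with frequency above 1% are treated as
common and excluded from burden testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import cnv_length, make_cnv_table
from .stats import FisherResult, bonferroni, fisher_exact

logger = logging.getLogger("isocohort")


@dataclass
class CNVFilterParams:
    # array profile
    array_min_probes: int = 3
    array_min_size_detect_bp: int = 1_000
    array_min_call_score: float = 15.0
    array_min_merge_score: float = 30.0
    array_min_size_keep_bp: int = 50_000
    # wes profile
    wes_min_qsome: float = 90.0
    wes_min_targets: int = 5
    # shared
    max_segdup_overlap: float = 0.5
    reciprocal_overlap_min: float = 0.80   # array frequency rule
    target_overlap_min: float = 0.50       # wes frequency rule
    rare_max_freq: float = 0.01
    merge_reciprocal_overlap: float = 0.5  # dual-caller merge rule

    def __post_init__(self) -> None:
        for f in (self.max_segdup_overlap, self.reciprocal_overlap_min,
                  self.target_overlap_min, self.rare_max_freq):
            if not 0 <= f <= 1:
                raise ValueError("fractions must be in [0, 1]")


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(overlap/len(a), overlap/len(b)) for 1-based inclusive intervals.

    Returns 0 for disjoint intervals; the caller is responsible for
    comparing only intervals on the same chromosome.
    """
    a1, a2 = a
    b1, b2 = b
    if a2 < a1 or b2 < b1:
        raise ValueError("zero-length or inverted interval")
    ov = min(a2, b2) - max(a1, b1) + 1
    if ov <= 0:
        return 0.0
    return min(ov / (a2 - a1 + 1), ov / (b2 - b1 + 1))


def segdup_overlap_fraction(start: int, end: int, segdups: pd.DataFrame, chrom: str) -> float:
    """Fraction of [start, end] covered by the union of segdup intervals."""
    sel = segdups[segdups["chrom"] == chrom]
    if sel.empty:
        return 0.0
    s = np.maximum(sel["start"].to_numpy(), start)
    e = np.minimum(sel["end"].to_numpy(), end)
    ivs = sorted((int(a), int(b)) for a, b in zip(s, e) if a <= b)
    covered, cur_s, cur_e = 0, None, None
    for a, b in ivs:
        if cur_e is None or a > cur_e + 1:
            if cur_e is not None:
                covered += cur_e - cur_s + 1
            cur_s, cur_e = a, b
        else:
            cur_e = max(cur_e, b)
    if cur_e is not None:
        covered += cur_e - cur_s + 1
    return covered / (end - start + 1)


def merge_array_callers(table: pd.DataFrame, params: CNVFilterParams) -> pd.DataFrame:
    """Merge same-sample, same-type array calls with reciprocal overlap >= 0.5.

    Stand-in for a dual-caller consensus step: matched calls are merged to
    their union interval with the maximum confidence score and summed
    probe count.
    """
    arr = table[table["source"] == "array"].reset_index(drop=True)
    rest = table[table["source"] != "array"]
    out_rows = []
    for (_, _, _), grp in arr.groupby(["sample_id", "chrom", "type"], sort=False):
        rows = grp.sort_values("start").to_dict("records")
        merged: list[dict] = []
        for r in rows:
            if merged and reciprocal_overlap(
                (merged[-1]["start"], merged[-1]["end"]), (r["start"], r["end"])
            ) >= params.merge_reciprocal_overlap:
                m = merged[-1]
                m["start"] = min(m["start"], r["start"])
                m["end"] = max(m["end"], r["end"])
                m["confidence"] = max(m["confidence"], r["confidence"])
                m["n_probes_or_targets"] += r["n_probes_or_targets"]
                m["segdup_overlap_fraction"] = max(m["segdup_overlap_fraction"],
                                                   r["segdup_overlap_fraction"])
            else:
                merged.append(dict(r))
        out_rows.extend(merged)
    merged_df = pd.DataFrame(out_rows, columns=arr.columns) if out_rows else arr.iloc[0:0]
    return make_cnv_table(pd.concat([merged_df, rest], ignore_index=True))


def filter_cnvs(
    table: pd.DataFrame,
    params: CNVFilterParams | None = None,
    segdups: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Apply the platform-specific QC cascades; returns kept calls + report.

    When a ``segdups`` interval table is given, the stored
    ``segdup_overlap_fraction`` is recomputed from it (union coverage).
    Unknown sources raise.
    """
    params = params or CNVFilterParams()
    t = table.copy().reset_index(drop=True)
    if not set(t["source"]) <= {"array", "wes"}:
        raise ValueError(f"unknown CNV source(s): {set(t['source']) - {'array', 'wes'}}")
    if segdups is not None:
        t["segdup_overlap_fraction"] = [
            segdup_overlap_fraction(int(r["start"]), int(r["end"]), segdups, r["chrom"])
            for _, r in t.iterrows()
        ]
    length = cnv_length(t)
    is_array = (t["source"] == "array").to_numpy()
    is_wes = ~is_array
    keep = np.ones(len(t), dtype=bool)
    report: dict[str, int] = {"n_input": len(t)}

    def drop(mask: np.ndarray, label: str) -> None:
        nonlocal keep
        report[label] = int((keep & mask).sum())
        keep &= ~mask

    # array cascade, in printed order
    drop(is_array & (t["n_probes_or_targets"].to_numpy() < params.array_min_probes),
         "array_min_probes")
    drop(is_array & (length <= params.array_min_size_detect_bp), "array_min_size_detect")
    drop(is_array & (t["confidence"].to_numpy() < params.array_min_call_score),
         "array_min_call_score")
    drop(is_array & (t["confidence"].to_numpy() < params.array_min_merge_score),
         "array_min_merge_score")
    drop(is_array & (length < params.array_min_size_keep_bp), "array_min_size_keep")
    drop(is_array & (t["segdup_overlap_fraction"].to_numpy() > params.max_segdup_overlap),
         "array_segdup")
    # wes cascade
    drop(is_wes & (t["confidence"].to_numpy() < params.wes_min_qsome), "wes_qsome")
    drop(is_wes & (t["n_probes_or_targets"].to_numpy() < params.wes_min_targets),
         "wes_targets")
    drop(is_wes & (t["segdup_overlap_fraction"].to_numpy() > params.max_segdup_overlap),
         "wes_segdup")
    report["n_kept"] = int(keep.sum())
    return t.loc[keep].reset_index(drop=True), report


def cnv_frequency(
    table: pd.DataFrame,
    reference_samples: list[str],
    overlap_min: float = 0.5,
) -> np.ndarray:
    """Cohort frequency of each call among ``reference_samples``.

    Frequency = (number of reference samples carrying >= 1 same-type call
    with reciprocal overlap >= ``overlap_min``) / n_reference.  A carrier's
    own calls count toward its own carrier status, so a unique call from a
    reference sample has frequency 1/n_reference.
    """
    ref = set(reference_samples)
    n_ref = len(ref)
    if n_ref == 0:
        raise ValueError("empty reference sample list")
    freqs = np.zeros(len(table))
    t = table.reset_index(drop=True)
    by_key: dict[tuple, list[tuple[int, int, str]]] = {}
    ref_rows = t[t["sample_id"].isin(ref)]
    for _, r in ref_rows.iterrows():
        by_key.setdefault((r["chrom"], r["type"]), []).append(
            (int(r["start"]), int(r["end"]), r["sample_id"])
        )
    for i, r in t.iterrows():
        matches = {
            sid for (s, e, sid) in by_key.get((r["chrom"], r["type"]), [])
            if reciprocal_overlap((int(r["start"]), int(r["end"])), (s, e)) >= overlap_min
        }
        freqs[i] = len(matches) / n_ref
    return freqs


def keep_one_sibling_per_family(samples: pd.DataFrame) -> pd.DataFrame:
    """Drop all but the first sibling of each family (deterministic order)."""
    sib = samples["role"] == "sibling"
    first = samples.loc[sib].sort_values("sample_id").groupby("family_id").head(1)
    return pd.concat([samples.loc[~sib], first]).sort_index()


def _intersects_gene(row: pd.Series, genes: pd.DataFrame) -> set[str]:
    sel = genes[(genes["chrom"] == row["chrom"]) &
                (genes["start"] <= row["end"]) & (genes["end"] >= row["start"])]
    return set(sel["gene"].str.upper())


def cnv_gene_hits(table: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Per-sample set of gene symbols whose exons are hit by >= 1 call."""
    hits: dict[str, set[str]] = {}
    for _, r in table.iterrows():
        hits.setdefault(r["sample_id"], set()).update(_intersects_gene(r, genes))
    return pd.Series(hits, dtype=object)


def cnv_geneset_burden(
    table: pd.DataFrame,
    genes: pd.DataFrame,
    gene_sets,
    case_samples: list[str],
    control_samples: list[str],
    cnv_type: str | None = None,
    set_names: list[str] | None = None,
    n_tests: int = 12,
) -> tuple[pd.DataFrame, FisherResult]:
    """One-sided Fisher carrier burden for a gene-set union, cases vs controls.

    ``table`` should contain rare, QC-passing calls only.  Deletions and
    duplications are tested separately via ``cnv_type``.  The Bonferroni
    family size defaults to the 12 tests of the standard report (2 types x
    6 gene categories).
    """
    t = table if cnv_type is None else table[table["type"] == cnv_type]
    union = gene_sets.union(set_names)
    hits = cnv_gene_hits(t, genes)

    def carriers(sample_list: list[str]) -> int:
        return sum(1 for s in sample_list if hits.get(s, set()) & union)

    a = carriers(case_samples)
    c = carriers(control_samples)
    n1, n2 = len(case_samples), len(control_samples)
    res = fisher_exact([[a, n1 - a], [c, n2 - c]], alternative="greater")
    summary = pd.DataFrame(dict(
        group=["case", "control"], n=[n1, n2], carriers=[a, c],
        proportion=[a / n1 if n1 else np.nan, c / n2 if n2 else np.nan],
    ))
    summary.attrs["p_bonferroni"] = bonferroni(res.p, n_tests)
    summary.attrs["n_tests"] = n_tests
    return summary, res
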