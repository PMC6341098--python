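"""Runs of homozygosity, ROH-based inbreeding, and pedigree kinship.

F_ROH is the fraction of the (SNP-spanned) autosomal genome lying inside
runs of homozygosity: a direct genomic estimate of autozygosity.  The
pedigree expectation is computed independently by the recursive kinship
algorithm, so simulated and expected inbreeding can be compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MISSING, AUTOSOMES, GenotypeMatrix, MarkerMap, Pedigree


@dataclass
class ROHParams:
    """Rules defining a run of homozygosity.

    A run is a maximal stretch of consecutive non-missing homozygous
    genotypes with at least ``min_consecutive_homozygous_snps`` markers.
    No heterozygous marker is tolerated inside a run; a missing call also
    terminates the run (conservative: no-call deserts never inflate ROH).
    Adjacent-marker gaps above ``max_gap_bp`` split runs, and a run whose
    SNP density is below one SNP per ``min_density_kb_per_snp`` kb is
    dropped.  ``min_length_bp`` defaults to 0 (no minimum length).
    """

    min_consecutive_homozygous_snps: int = 50
    min_density_kb_per_snp: float = 5000.0
    min_length_bp: int = 0
    max_gap_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if self.min_consecutive_homozygous_snps < 2:
            raise ValueError("min_consecutive_homozygous_snps must be >= 2")
        if self.min_density_kb_per_snp <= 0:
            raise ValueError("density must be positive")


@dataclass
class ROHSegment:
    sample_id: str
    chrom: str
    start: int   # position of first SNP in the run
    end: int     # position of last SNP in the run
    n_snps: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def detect_roh(gm: GenotypeMatrix, sample: str, params: ROHParams | None = None) -> list[ROHSegment]:
    """Detect ROH for one sample over the autosomal markers of ``gm``.

    Markers must be position-sorted within chromosome (enforced by
    MarkerMap).  Segment span is first-to-last SNP position.
    """
    params = params or ROHParams()
    i = gm.samples.index(sample)
    g = gm.genotypes[i]
    chroms = gm.markers.chroms
    pos = gm.markers.positions
    segments: list[ROHSegment] = []
    for chrom in dict.fromkeys(chroms):
        if chrom not in AUTOSOMES:
            continue
        idx = np.flatnonzero(chroms == chrom)
        gg = g[idx]
        pp = pos[idx]
        if np.any(np.diff(pp) <= 0):
            raise ValueError(f"markers not sorted on chromosome {chrom}")
        hom = (gg == 0) | (gg == 2)
        # het or missing markers break runs; so do large inter-marker gaps
        hj = np.flatnonzero(hom)
        if hj.size == 0:
            continue
        breaks = (np.diff(hj) != 1) | (pp[hj[1:]] - pp[hj[:-1]] > params.max_gap_bp)
        for run in np.split(hj, np.flatnonzero(breaks) + 1):
            _emit(segments, sample, chrom, pp, int(run[0]), int(run[-1]) + 1, params)
    return segments


def _emit(segments, sample, chrom, pp, start, stop, params) -> None:
    n = stop - start
    if n < params.min_consecutive_homozygous_snps:
        return
    span = int(pp[stop - 1] - pp[start] + 1)
    if span < params.min_length_bp:
        return
    # density rule: at least one SNP per min_density_kb_per_snp kb of span
    if span / 1000.0 > n * params.min_density_kb_per_snp:
        return
    segments.append(ROHSegment(sample, str(chrom), int(pp[start]), int(pp[stop - 1]), n))


def merge_segments(segments: list[ROHSegment]) -> list[ROHSegment]:
    """Merge overlapping/adjacent segments per (sample, chromosome)."""
    out: list[ROHSegment] = []
    keyf = lambda s: (s.sample_id, s.chrom, s.start)
    for seg in sorted(segments, key=keyf):
        if out and out[-1].sample_id == seg.sample_id and out[-1].chrom == seg.chrom \
                and seg.start <= out[-1].end + 1:
            prev = out[-1]
            out[-1] = ROHSegment(prev.sample_id, prev.chrom, prev.start,
                                 max(prev.end, seg.end), prev.n_snps + seg.n_snps)
        else:
            out.append(seg)
    return out


@dataclass
class InbreedingResult:
    sample_id: str
    f_roh: float
    total_roh_bp: int
    autosome_denominator_bp: int


def autosome_denominator(markers: MarkerMap) -> int:
    """SNP-spanned autosomal length: sum over autosomes of (last - first + 1)."""
    t = markers.table
    t = t[t["chrom"].isin(AUTOSOMES)]
    if t.empty:
        raise ValueError("marker map has no autosomal markers")
    return int((t.groupby("chrom")["pos"].max() - t.groupby("chrom")["pos"].min() + 1).sum())


def inbreeding_coefficient(segments: list[ROHSegment], markers: MarkerMap,
                           sample_id: str | None = None) -> InbreedingResult:
    """F_ROH = total merged ROH length / SNP-spanned autosome length."""
    denom = autosome_denominator(markers)
    merged = merge_segments(segments)
    total = sum(s.length for s in merged)
    sid = sample_id if sample_id is not None else (merged[0].sample_id if merged else "")
    return InbreedingResult(sid, total / denom, total, denom)


def froh_per_sample(gm: GenotypeMatrix, params: ROHParams | None = None) -> pd.DataFrame:
    """Convenience: per-sample ROH detection and F_ROH over the whole matrix."""
    rows = []
    for s in gm.samples:
        segs = detect_roh(gm, s, params)
        res = inbreeding_coefficient(segs, gm.markers, sample_id=s)
        rows.append(dict(sample_id=s, f_roh=res.f_roh, total_roh_bp=res.total_roh_bp,
                         n_segments=len(merge_segments(segs))))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pedigree kinship and expected inbreeding

def kinship(pedigree: Pedigree, a: str, b: str, _memo: dict | None = None) -> float:
    """Kinship coefficient phi(a, b) by the standard recursion.

    phi(a, a) = (1 + F_a) / 2 with F_a the inbreeding of a;
    phi(a, b) = (phi(father_a, b) + phi(mother_a, b)) / 2 recursing on the
    individual further from the founders (never an ancestor of the other).
    Missing parents contribute kinship 0.
    """
    memo = _memo if _memo is not None else {}

    def phi(x: str, y: str) -> float:
        key = (x, y) if x <= y else (y, x)
        if key in memo:
            return memo[key]
        if x == y:
            fa, mo = pedigree.members[x]
            f_x = phi(fa, mo) if fa is not None and mo is not None else 0.0
            val = 0.5 * (1.0 + f_x)
        else:
            # recurse on the deeper individual: it cannot be the other's ancestor
            if pedigree.depth(x) < pedigree.depth(y):
                x, y = y, x
            fa, mo = pedigree.members[x]
            val = 0.0
            if fa is not None:
                val += 0.5 * phi(fa, y)
            if mo is not None:
                val += 0.5 * phi(mo, y)
        memo[key] = val
        return val

    return phi(a, b)


def pedigree_inbreeding(pedigree: Pedigree, individual: str) -> float:
    """Expected inbreeding F of ``individual`` = kinship of its parents.

    A child of second cousins has F = 1/64; of first cousins, 1/16.
    Individuals with a missing parent get F = 0.
    """
    if individual not in pedigree.members:
        raise KeyError(f"{individual} not in pedigree")
    fa, mo = pedigree.members[individual]
    if fa is None or mo is None:
        return 0.0
    return kinship(pedigree, fa, mo)


def average_siblings_by_family(values: pd.DataFrame, samples: pd.DataFrame,
                               value_col: str = "f_roh") -> pd.DataFrame:
    """Collapse sibling rows to one per family by averaging ``value_col``.

    Non-sibling rows pass through unchanged; used before group tests so a
    large sibship does not dominate its group.
    """
    merged = values.merge(samples[["sample_id", "family_id", "role"]], on="sample_id")
    sibs = merged[merged["role"] == "sibling"]
    rest = merged[merged["role"] != "sibling"]
    fam = (
        sibs.groupby("family_id", as_index=False)
        .agg({value_col: "mean"})
        .assign(role="sibling")
    )
    fam["sample_id"] = "family:" + fam["family_id"].astype(str)
    cols = ["sample_id", "family_id", "role", value_col]
    return pd.concat([rest[cols], fam[cols]], ignore_index=True)
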