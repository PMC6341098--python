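"""Population structure: marker QC, IBS distance, classical MDS, exclusions.

The pairwise distance between two individuals is

    d = 1 - (0.5 * IBS1 + IBS2) / N

where IBS1 and IBS2 count the markers at which the pair shares exactly one
or two alleles identical by state and N is the number of markers called in
both individuals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix

logger = logging.getLogger("isocohort")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test

def hwe_exact_test(n_aa_major: int, n_het: int, n_aa_minor: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value for one biallelic marker.

    Sums the conditional probabilities (given allele counts) of all
    heterozygote counts whose probability does not exceed that of the
    observed count.  Monomorphic markers return 1.

    Parameters are the three genotype counts (order of the two homozygote
    classes does not matter).
    """
    counts = (n_aa_major, n_het, n_aa_minor)
    if any(c < 0 for c in counts):
        raise ValueError("negative genotype count")
    n = sum(counts)
    if n == 0:
        raise ValueError("empty marker")
    n_minor = min(2 * n_aa_major + n_het, 2 * n_aa_minor + n_het)
    if n_minor == 0:
        return 1.0

    # P(het = h | allele counts) up to a constant, via the standard recurrence
    h_min = n_minor % 2
    h_max = min(n_minor, 2 * n - n_minor)
    h0 = h_max - ((h_max - h_min) % 2)  # largest attainable het count of right parity
    probs = {h0: 1.0}
    h = h0
    while h - 2 >= h_min:
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        # p(h-2) / p(h) = h*(h-1) / (4*(hom_minor+1)*(hom_major+1))
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_minor + 1) * (hom_major + 1))
        h -= 2
    total = sum(probs.values())
    obs = probs.get(n_het)
    if obs is None:
        raise ValueError(f"heterozygote count {n_het} impossible for allele counts")
    threshold = obs * (1.0 + 1e-12)
    return min(1.0, sum(p for p in probs.values() if p <= threshold) / total)


# ---------------------------------------------------------------------------
# Marker QC

@dataclass
class QCParams:
    """Thresholds for marker QC, applied call rate -> MAF -> HWE -> LD."""

    min_call_rate: float = 0.95
    min_maf: float = 0.05
    hwe_p_threshold: float = 1e-6
    ld_r_threshold: float | None = 0.5
    ld_window_snps: int = 50
    ld_step_snps: int = 5

    def __post_init__(self) -> None:
        if not (0 <= self.min_call_rate <= 1 and 0 <= self.min_maf <= 0.5):
            raise ValueError("call rate / MAF thresholds out of range")
        if self.ld_r_threshold is not None and not 0 <= self.ld_r_threshold <= 1:
            raise ValueError("ld_r_threshold out of range")
        if self.ld_window_snps <= self.ld_step_snps or self.ld_step_snps < 1:
            raise ValueError("require window > step >= 1")


#: QC profile used before ancestry analysis (perfect call rate, lenient HWE).
ANCESTRY_PROFILE = QCParams(min_call_rate=1.0, min_maf=0.0, hwe_p_threshold=1e-3,
                            ld_r_threshold=None)
#: QC profile used before inbreeding estimation.
INBREEDING_PROFILE = QCParams(min_call_rate=0.95, min_maf=0.05, hwe_p_threshold=1e-6,
                              ld_r_threshold=0.5)
#: QC profile used before association testing (no LD prune).
GWAS_PROFILE = QCParams(min_call_rate=0.90, min_maf=0.05, hwe_p_threshold=1e-6,
                        ld_r_threshold=None)


def _pairwise_complete_r(x: np.ndarray, y: np.ndarray) -> float:
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    if xv.std() == 0 or yv.std() == 0:
        return 0.0
    return float(np.corrcoef(xv, yv)[0, 1])


def marker_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker call rate, MAF and HWE p-value."""
    g = gm.genotypes
    called = g != MISSING
    n_called = called.sum(axis=0)
    call_rate = n_called / gm.n_samples
    alt = np.where(called, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        af = np.where(n_called > 0, alt / np.maximum(2 * n_called, 1), np.nan)
    maf = np.minimum(af, 1 - af)
    hwe_p = np.ones(gm.n_markers)
    for j in range(gm.n_markers):
        if n_called[j] == 0:
            continue
        col = g[:, j]
        n0 = int(((col == 0)).sum())
        n1 = int(((col == 1)).sum())
        n2 = int(((col == 2)).sum())
        hwe_p[j] = hwe_exact_test(n0, n1, n2)
    return pd.DataFrame(dict(marker_id=gm.markers.marker_ids, call_rate=call_rate,
                             maf=maf, hwe_p=hwe_p))


def _ld_prune(gm: GenotypeMatrix, params: QCParams) -> np.ndarray:
    """Greedy sliding-window LD prune; returns boolean keep mask."""
    keep = np.ones(gm.n_markers, dtype=bool)
    g = gm.genotypes
    chroms = gm.markers.chroms
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        start = 0
        while start < len(idx):
            window = idx[start:start + params.ld_window_snps]
            for a_pos in range(len(window)):
                ja = window[a_pos]
                if not keep[ja]:
                    continue
                for b_pos in range(a_pos + 1, len(window)):
                    jb = window[b_pos]
                    if not keep[jb]:
                        continue
                    r = _pairwise_complete_r(g[:, ja], g[:, jb])
                    if abs(r) > params.ld_r_threshold:
                        keep[jb] = False
            if start + params.ld_window_snps >= len(idx):
                break
            start += params.ld_step_snps
    return keep


def qc_filter_markers(gm: GenotypeMatrix, params: QCParams) -> tuple[GenotypeMatrix, dict]:
    """Drop markers failing call rate, MAF, HWE; then greedy LD prune.

    Returns the filtered matrix and a report of counts removed per
    criterion, in application order.
    """
    stats = marker_stats(gm)
    keep = np.ones(gm.n_markers, dtype=bool)
    report: dict[str, int] = {}

    fail_cr = stats["call_rate"].to_numpy() < params.min_call_rate
    report["call_rate"] = int((keep & fail_cr).sum())
    keep &= ~fail_cr

    fail_maf = np.nan_to_num(stats["maf"].to_numpy(), nan=0.0) < params.min_maf
    report["maf"] = int((keep & fail_maf).sum())
    keep &= ~fail_maf

    fail_hwe = stats["hwe_p"].to_numpy() < params.hwe_p_threshold
    report["hwe"] = int((keep & fail_hwe).sum())
    keep &= ~fail_hwe

    sub = gm.subset_markers(keep)
    if params.ld_r_threshold is not None and sub.n_markers > 1:
        ld_keep = _ld_prune(sub, params)
        report["ld"] = int((~ld_keep).sum())
        sub = sub.subset_markers(ld_keep)
    else:
        report["ld"] = 0
    report["n_input"] = gm.n_markers
    report["n_kept"] = sub.n_markers
    if sub.n_markers == 0:
        raise ValueError(f"all markers removed by QC: {report}")
    return sub, report


# ---------------------------------------------------------------------------
# IBS distance and classical MDS

@dataclass
class IBSMatrix:
    """Symmetric pairwise IBS distance matrix in [0, 1] with sample order."""

    samples: list[str]
    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        n = len(self.samples)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("nonzero diagonal")
        if d.min() < -1e-12 or d.max() > 1 + 1e-12:
            raise ValueError("distances outside [0, 1]")
        self.distances = d

    def similarity(self) -> np.ndarray:
        return 1.0 - self.distances


def ibs_distance_matrix(gm: GenotypeMatrix) -> IBSMatrix:
    """Pairwise IBS distance 1 - (0.5*IBS1 + IBS2)/N over shared called markers."""
    if gm.n_samples < 2:
        raise ValueError("need at least two samples")
    g = gm.genotypes
    ind = [(g == k).astype(float) for k in (0, 1, 2)]
    valid = (g != MISSING).astype(float)
    n_shared = valid @ valid.T
    ibs0 = ind[0] @ ind[2].T + ind[2] @ ind[0].T
    ibs1 = ind[0] @ ind[1].T + ind[1] @ ind[0].T + ind[1] @ ind[2].T + ind[2] @ ind[1].T
    if np.any((n_shared == 0) & ~np.eye(gm.n_samples, dtype=bool)):
        ii, jj = np.argwhere((n_shared == 0) & ~np.eye(gm.n_samples, dtype=bool))[0]
        raise ValueError(f"no shared called markers for pair ({gm.samples[ii]}, {gm.samples[jj]})")
    dist = (ibs0 + 0.5 * ibs1) / n_shared
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 1.0)
    return IBSMatrix(list(gm.samples), dist)


def classical_mds(ibs: IBSMatrix, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling of a distance matrix.

    Double-centres the squared distances, takes the top-k eigenpairs and
    scales eigenvectors by the square root of their (nonnegative)
    eigenvalues.  Components are ordered by decreasing eigenvalue; each
    eigenvector's sign is fixed by making its largest-magnitude loading
    positive.  If fewer than k positive eigenvalues exist the returned
    matrix has fewer columns (with a logged warning).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d2 = ibs.distances ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-12 if vals.max() > 0 else np.zeros_like(vals, bool)
    n_pos = int(pos.sum())
    if n_pos < k:
        logger.warning("classical_mds: only %d positive eigenvalues, truncating k=%d", n_pos, k)
    k_eff = min(k, n_pos)
    coords = vecs[:, :k_eff] * np.sqrt(vals[:k_eff])
    for c in range(k_eff):
        if coords[np.argmax(np.abs(coords[:, c])), c] < 0:
            coords[:, c] = -coords[:, c]
    return coords


# ---------------------------------------------------------------------------
# Relatedness and outlier exclusion

@dataclass
class ExclusionReport:
    related: list[str] = field(default_factory=list)
    outliers: list[str] = field(default_factory=list)

    @property
    def excluded(self) -> list[str]:
        return sorted(set(self.related) | set(self.outliers))


def flag_related_or_outlier(
    ibs: IBSMatrix,
    call_rates: np.ndarray | None = None,
    relatedness_threshold: float = 0.9,
    mds_outlier_z: float = 6.0,
) -> ExclusionReport:
    """Flag one member of each highly similar pair plus MDS outliers.

    For pairs with IBS similarity (1 - distance) above the threshold the
    member with the lower call rate is flagged (tie: the lexicographically
    larger id, so the smaller id is retained).  Outliers are samples whose
    robust z-score (median / 1.4826*MAD) exceeds ``mds_outlier_z`` on
    either of the first two MDS components.
    """
    n = len(ibs.samples)
    cr = np.ones(n) if call_rates is None else np.asarray(call_rates, dtype=float)
    sim = ibs.similarity()
    report = ExclusionReport()
    flagged: set[str] = set()
    for i in range(n):
        for j in range(i + 1, n):
            if sim[i, j] > relatedness_threshold:
                si, sj = ibs.samples[i], ibs.samples[j]
                if cr[i] < cr[j]:
                    drop = si
                elif cr[j] < cr[i]:
                    drop = sj
                else:
                    drop = max(si, sj)
                flagged.add(drop)
    report.related = sorted(flagged)

    coords = classical_mds(ibs, k=2)
    for c in range(coords.shape[1]):
        x = coords[:, c]
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        scale = 1.4826 * mad
        if scale == 0:
            continue
        z = np.abs(x - med) / scale
        for i in np.flatnonzero(z > mds_outlier_z):
            if ibs.samples[i] not in report.outliers:
                report.outliers.append(ibs.samples[i])
    report.outliers = sorted(report.outliers)
    return report
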