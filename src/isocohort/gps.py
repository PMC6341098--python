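"""Genome-wide polygenic scoring by LD clumping + p-value thresholding.

The score of an individual is the weighted sum of risk-allele dosages
over the clumped markers passing the p-value threshold, with the weights
taken from external GWAS summary statistics.  A scan over a grid of
thresholds picks the one maximizing the squared Pearson correlation
between score and case status (the "best-fit" threshold).  Genotypes are
never imputed: missing dosages are simply excluded, which is why the
per-allele average normalization is the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix

logger = logging.getLogger("isocohort")


@dataclass
class GPSConfig:
    threshold_start: float = 0.0
    threshold_step: float = 0.01
    threshold_end: float = 1.0
    clump_r2: float = 0.1
    clump_window_kb: float = 250.0
    score_normalization: str = "per_allele_average"  # or "sum"

    def __post_init__(self) -> None:
        if not 0 <= self.clump_r2 <= 1:
            raise ValueError("clump_r2 must be in [0, 1]")
        if self.score_normalization not in ("sum", "per_allele_average"):
            raise ValueError("unknown score normalization")

    def grid(self) -> np.ndarray:
        g = np.arange(self.threshold_start, self.threshold_end + self.threshold_step / 2,
                      self.threshold_step)
        return np.round(g[(g > 0) & (g <= 1)], 10)


@dataclass
class GPSResult:
    scores: pd.Series               # at the best threshold
    best_threshold: float
    r2_at_best: float
    scan: pd.DataFrame              # threshold -> r2, n_markers


def match_summary_to_markers(summary: pd.DataFrame, gm: GenotypeMatrix) -> pd.DataFrame:
    """Resolve summary records against the marker map.

    Effect allele equal to allele_b keeps beta; equal to allele_a flips
    its sign (the dosage counts allele_b).  Unresolvable records are
    dropped with a logged count.
    """
    mk = gm.markers.table.set_index("marker_id")
    rows = []
    n_dropped = 0
    for _, r in summary.iterrows():
        mid = r["marker_id"]
        if mid not in mk.index:
            n_dropped += 1
            continue
        a, b = mk.at[mid, "allele_a"], mk.at[mid, "allele_b"]
        if r["effect_allele"] == b:
            beta = r["beta"]
        elif r["effect_allele"] == a:
            beta = -r["beta"]
        else:
            n_dropped += 1
            continue
        rows.append(dict(marker_id=mid, beta=float(beta), p=float(r["p"])))
    if n_dropped:
        logger.info("match_summary_to_markers: dropped %d unresolvable records", n_dropped)
    if not rows:
        raise ValueError("no overlap between summary statistics and genotype markers")
    return pd.DataFrame(rows)


def _dosage_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv, yv = x[ok].astype(float), y[ok].astype(float)
    if xv.std() == 0 or yv.std() == 0:
        return 0.0
    return float(np.corrcoef(xv, yv)[0, 1] ** 2)


def clump(summary: pd.DataFrame, gm: GenotypeMatrix, config: GPSConfig | None = None
          ) -> pd.DataFrame:
    """Greedy LD clumping: keep the best-p marker, drop correlated neighbours.

    Markers are visited by ascending p; each retained index marker removes
    all markers within ``clump_window_kb`` whose dosage r^2 with it exceeds
    ``clump_r2``.
    """
    config = config or GPSConfig()
    matched = match_summary_to_markers(summary, gm)
    ids = list(gm.markers.marker_ids)
    pos = dict(zip(ids, gm.markers.positions))
    chrom = dict(zip(ids, gm.markers.chroms))
    col = {mid: ids.index(mid) for mid in matched["marker_id"]}

    order = matched.sort_values(["p", "marker_id"], kind="stable")
    alive = set(matched["marker_id"])
    kept = []
    win = config.clump_window_kb * 1000.0
    for _, r in order.iterrows():
        mid = r["marker_id"]
        if mid not in alive:
            continue
        kept.append(mid)
        alive.discard(mid)
        for other in list(alive):
            if chrom[other] != chrom[mid] or abs(pos[other] - pos[mid]) > win:
                continue
            if _dosage_r2(gm.genotypes[:, col[mid]], gm.genotypes[:, col[other]]) > config.clump_r2:
                alive.discard(other)
    return matched[matched["marker_id"].isin(kept)].reset_index(drop=True)


def compute_gps(
    gm: GenotypeMatrix,
    clumped: pd.DataFrame,
    threshold: float,
    config: GPSConfig | None = None,
) -> pd.Series:
    """Per-sample polygenic score at one p-value threshold.

    ``sum`` mode: sum of beta * dosage over included non-missing markers;
    ``per_allele_average`` divides by 2 x (number of included non-missing
    markers for that sample).  Samples with no usable marker score 0 with
    a warning.
    """
    config = config or GPSConfig()
    inc = clumped[clumped["p"] <= threshold]
    if inc.empty:
        raise ValueError(f"threshold {threshold} excludes all markers")
    ids = list(gm.markers.marker_ids)
    cols = [ids.index(m) for m in inc["marker_id"]]
    g = gm.genotypes[:, cols].astype(float)
    beta = inc["beta"].to_numpy()
    called = g != MISSING
    contrib = np.where(called, g, 0.0) * beta
    raw = contrib.sum(axis=1)
    if config.score_normalization == "sum":
        scores = raw
    else:
        n_called = called.sum(axis=1)
        with np.errstate(invalid="ignore"):
            scores = raw / np.maximum(2 * n_called, 1)
        if (n_called == 0).any():
            logger.warning("compute_gps: %d samples with zero usable markers score 0",
                           int((n_called == 0).sum()))
    return pd.Series(scores, index=gm.samples, name=f"gps@{threshold}")


def threshold_scan(
    gm: GenotypeMatrix,
    summary: pd.DataFrame,
    phenotype: np.ndarray,
    config: GPSConfig | None = None,
) -> GPSResult:
    """Scan the threshold grid; best threshold maximizes r2 (ties: smallest).

    ``phenotype`` is the 0/1 case status aligned with ``gm.samples``; r2 is
    the squared Pearson correlation between score and phenotype.
    """
    config = config or GPSConfig()
    y = np.asarray(phenotype, dtype=float)
    if np.std(y) == 0:
        raise ValueError("constant phenotype")
    clumped = clump(summary, gm, config)
    rows = []
    best = (None, -np.inf)
    best_scores = None
    for thr in config.grid():
        inc = clumped[clumped["p"] <= thr]
        if inc.empty:
            continue
        scores = compute_gps(gm, clumped, thr, config)
        s = scores.to_numpy()
        r2 = 0.0 if np.std(s) == 0 else float(np.corrcoef(s, y)[0, 1] ** 2)
        rows.append(dict(threshold=float(thr), r2=r2, n_markers=len(inc)))
        if r2 > best[1]:
            best = (float(thr), r2)
            best_scores = scores
    if best_scores is None:
        raise ValueError("no grid threshold includes any marker")
    scan = pd.DataFrame(rows)
    return GPSResult(best_scores, best[0], best[1], scan)
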