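"""Exact and rank-based statistics shared by the analysis stages.

Fisher's exact test reports the conditional maximum-likelihood odds ratio
(the estimate tied to the noncentral hypergeometric likelihood of a 2x2
table with fixed margins) and the exact confidence interval obtained by
inverting the conditional test at 2.5% per tail — the convention of
classical epidemiological software, which differs from the sample odds
ratio ad/(bc).

The covariate-adjusted Mann-Whitney test residualizes the response on the
covariates by ordinary least squares (intercept included, fitted jointly
on both groups) and applies the rank test to the residuals; with no
covariates it reduces exactly to the plain test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import contingency

from .datamodel import MISSING, GenotypeMatrix

logger = logging.getLogger("isocohort")


@dataclass
class FisherResult:
    p: float
    odds_ratio: float | None       # conditional MLE; None when undefined
    ci95: tuple[float, float] | None
    table: tuple[int, int, int, int]


def fisher_exact(table, alternative: str = "two_sided") -> FisherResult:
    """Fisher's exact test with conditional-MLE OR and exact 95% CI.

    ``table`` is [[a, b], [c, d]] with rows = groups, columns = outcome.
    A zero row or column margin yields p = 1 and an undefined OR.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of nonnegative counts")
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
    a, b, c, d = int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1])
    if min(a + b, c + d, a + c, b + d) == 0:
        return FisherResult(1.0, None, None, (a, b, c, d))
    p = float(sps.fisher_exact(t, alternative=alt)[1])
    orr = contingency.odds_ratio(t, kind="conditional")
    ci = orr.confidence_interval(0.95)
    return FisherResult(p, float(orr.statistic), (float(ci.low), float(ci.high)), (a, b, c, d))


@dataclass
class AdjustedRankTestResult:
    u: float
    p: float
    n1: int
    n2: int
    covariates: list[str]


def residualize(values: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """OLS residuals of ``values`` on covariates (intercept included)."""
    y = np.asarray(values, dtype=float)
    if covariates is None or np.size(covariates) == 0:
        return y
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    keep = c.std(axis=0) > 0    # constant columns are collinear with the intercept
    if not keep.all():
        logger.info("residualize: dropped %d constant covariate column(s)",
                    int((~keep).sum()))
    c = c[:, keep]
    if c.shape[1] == 0:
        return y
    x = np.column_stack([np.ones(len(y)), c])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("covariate matrix (with intercept) is rank deficient")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def adjusted_mannwhitney(
    values,
    group1_mask,
    covariates=None,
    alternative: str = "greater",
    covariate_names: list[str] | None = None,
) -> AdjustedRankTestResult:
    """Mann-Whitney U test of group1 vs group2 on covariate-adjusted values.

    ``alternative='greater'`` tests whether group1 values are
    stochastically larger.  Midranks for ties, normal approximation with
    tie-corrected variance and continuity correction.  U is reported for
    group1.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(group1_mask, dtype=bool)
    n1, n2 = int(mask.sum()), int((~mask).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    resid = residualize(values, covariates)
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
    res = sps.mannwhitneyu(resid[mask], resid[~mask], alternative=alt,
                           method="asymptotic", use_continuity=True)
    return AdjustedRankTestResult(float(res.statistic), float(res.pvalue), n1, n2,
                                  list(covariate_names or []))


# ---------------------------------------------------------------------------
# Single-variant GWAS chi-square

def _chi2_2x2(t: np.ndarray) -> float:
    rs = t.sum(axis=1, keepdims=True)
    cs = t.sum(axis=0, keepdims=True)
    n = t.sum()
    if n == 0 or (rs == 0).any() or (cs == 0).any():
        return 0.0
    e = rs @ cs / n
    return float(((t - e) ** 2 / e).sum())


def gwas_single_variant(gm: GenotypeMatrix, case_mask, model: str = "allelic") -> pd.DataFrame:
    """Per-marker 1-df chi-square association p-values (no continuity correction).

    Models: ``allelic`` (2x2 allele-count table, two alleles per called
    sample), ``dominant`` (carrier of >= 1 ALT) and ``recessive``
    (homozygous ALT).  Markers with a zero margin (monomorphic) get p = 1.
    """
    if model not in ("allelic", "dominant", "recessive"):
        raise ValueError(f"unknown model {model!r}")
    case_mask = np.asarray(case_mask, dtype=bool)
    g = gm.genotypes
    rows = []
    for j in range(gm.n_markers):
        col = g[:, j]
        called = col != MISSING
        stats_rows = []
        for grp_mask in (case_mask, ~case_mask):
            sel = col[grp_mask & called]
            if model == "allelic":
                pos = int(sel.sum())
                neg = int(2 * len(sel) - pos)
            elif model == "dominant":
                pos = int((sel >= 1).sum())
                neg = int(len(sel) - pos)
            else:
                pos = int((sel == 2).sum())
                neg = int(len(sel) - pos)
            stats_rows.append((pos, neg))
        t = np.array(stats_rows, dtype=float)
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            chi2, p = 0.0, 1.0
        else:
            chi2 = _chi2_2x2(t)
            p = float(sps.chi2.sf(chi2, df=1))
        rows.append(dict(marker_id=gm.markers.marker_ids[j], chi2=chi2, p=p))
    return pd.DataFrame(rows)


def collapsing_carrier_test(
    table, gene: str, case_mask, maf_window: tuple[float, float] = (1e-6, 0.05),
    alternative: str = "greater",
) -> FisherResult:
    """Collapsing (CMC-style) carrier burden test for one gene.

    A carrier holds >= 1 qualifying allele at any variant of the gene whose
    cohort allele frequency falls inside ``maf_window``; carrier counts are
    compared between groups with Fisher's exact test.
    """
    case_mask = np.asarray(case_mask, dtype=bool)
    in_gene = (table.variants["gene"].str.upper() == gene.upper()).to_numpy()
    af = table.cohort_allele_frequency()
    qualifying = in_gene & (af >= maf_window[0]) & (af <= maf_window[1])
    carrier = (table.gt[qualifying, :] > 0).any(axis=0) if qualifying.any() \
        else np.zeros(len(table.samples), dtype=bool)
    a = int(carrier[case_mask].sum())
    b = int(case_mask.sum()) - a
    c = int(carrier[~case_mask].sum())
    d = int((~case_mask).sum()) - c
    return fisher_exact([[a, b], [c, d]], alternative=alternative)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def manhattan_qq_tables(pvals, markers=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready tables: genome-ordered -log10 p, and expected-vs-observed quantiles."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    manhattan = pd.DataFrame(dict(neg_log10_p=-np.log10(p)))
    if markers is not None:
        manhattan.insert(0, "chrom", markers.chroms)
        manhattan.insert(1, "pos", markers.positions)
    obs = -np.log10(np.sort(p))
    exp = -np.log10((np.arange(1, p.size + 1) - 0.5) / p.size)
    qq = pd.DataFrame(dict(expected=exp, observed=obs))
    return manhattan, qq
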