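"""Post-hoc power for the study's one-sided two-group comparisons.

Mann-Whitney power uses the asymptotic-relative-efficiency correction of
the two-sample t-test: the standardized effect d is scaled by sqrt(ARE)
(ARE = 3/pi for a normal parent distribution, 0.864 for the minimum over
continuous distributions), and power is computed from the noncentral t
distribution with n1 + n2 - 2 degrees of freedom.  Fisher-exact power is
computed by full enumeration of the two binomial outcome distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.optimize import brentq

from .stats import fisher_exact

ARE_NORMAL = 3.0 / math.pi
ARE_MIN = 0.864

_PARENTS = {"normal": ARE_NORMAL, "min_are": ARE_MIN}


@dataclass
class PowerSpec:
    """Two-group design for a Mann-Whitney power computation.

    ``d`` is Cohen's standardized mean difference; ``tails`` defaults to 1
    (directional enrichment hypotheses); ``parent_distribution`` selects
    the A.R.E. used for the rank-test correction.
    """

    n1: int
    n2: int
    d: float
    alpha: float = 0.05
    tails: int = 1
    parent_distribution: str = "normal"

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("need n1, n2 >= 2")
        if not 0 < self.alpha <= 0.5:
            raise ValueError("alpha must be in (0, 0.5]")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")
        if self.parent_distribution not in _PARENTS:
            raise ValueError(f"unknown parent distribution {self.parent_distribution!r}")

    @property
    def are(self) -> float:
        return _PARENTS[self.parent_distribution]


def wmw_power(spec: PowerSpec) -> float:
    """Achieved power of the one- or two-sided Mann-Whitney test.

    Effective effect d_eff = d * sqrt(ARE); noncentrality
    ncp = d_eff / sqrt(1/n1 + 1/n2); power is the rejection probability of
    the t test with df = n1 + n2 - 2 under that noncentrality.  At d = 0
    the power equals alpha.
    """
    df = spec.n1 + spec.n2 - 2
    if df < 1:
        raise ValueError("degrees of freedom < 1")
    d_eff = spec.d * math.sqrt(spec.are)
    ncp = d_eff / math.sqrt(1.0 / spec.n1 + 1.0 / spec.n2)
    t_crit = sps.t.ppf(1.0 - spec.alpha / spec.tails, df)
    power = float(sps.nct.sf(t_crit, df, ncp))
    if spec.tails == 2:
        power += float(sps.nct.cdf(-t_crit, df, ncp))
    return power


def wmw_required_d(
    n1: int,
    n2: int,
    target_power: float = 0.8,
    alpha: float = 0.05,
    tails: int = 1,
    parent_distribution: str = "normal",
) -> float:
    """Effect size d needed to reach ``target_power`` (monotone root solve)."""
    if not alpha < target_power < 1:
        raise ValueError("target power must lie in (alpha, 1)")

    def gap(d: float) -> float:
        return wmw_power(PowerSpec(n1, n2, d, alpha, tails, parent_distribution)) - target_power

    hi = 1.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e3:
            raise ValueError("target power unattainable")
    return float(brentq(gap, 0.0, hi, xtol=1e-9))


def fisher_power(
    p1: float,
    p2: float,
    n1: int,
    n2: int,
    alpha: float = 0.05,
    tails: int = 1,
) -> float:
    """Exact power of Fisher's test for two binomial proportions.

    Enumerates all (x1, x2) outcomes, sums the joint binomial
    probabilities of the tables rejected at ``alpha``.  One-sided tests
    the alternative p1 > p2.  Under p1 = p2 the result never exceeds the
    nominal level (the exact test is conservative).
    """
    alt = "greater" if tails == 1 else "two_sided"
    pmf1 = sps.binom.pmf(np.arange(n1 + 1), n1, p1)
    pmf2 = sps.binom.pmf(np.arange(n2 + 1), n2, p2)
    power = 0.0
    for x1 in range(n1 + 1):
        for x2 in range(n2 + 1):
            res = fisher_exact([[x1, n1 - x1], [x2, n2 - x2]], alternative=alt)
            if res.p <= alpha:
                power += float(pmf1[x1] * pmf2[x2])
    return power


def round_half_up(x: float, decimals: int = 2) -> float:
    """Reporting convention: round half away from zero to ``decimals``."""
    factor = 10 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)
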