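"""Fisher exact (enumeration oracle, CI inversion), adjusted Mann-Whitney,
GWAS chi-square, Bonferroni, Manhattan/QQ tables."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from isocohort import stats as ist
from conftest import make_gm


# ---------------------------------------------------------------------------
# Fisher exact vs hypergeometric enumeration oracle

def fisher_oracle(a, b, c, d, alternative="two_sided"):
    """Exact p by direct enumeration over tables with the observed margins."""
    r1, c1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (math.comb(c1, x) * math.comb(n - c1, r1 - x)) / math.comb(n, r1)

    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    obs = prob(a)
    if alternative == "greater":
        return sum(prob(x) for x in range(a, hi + 1))
    if alternative == "less":
        return sum(prob(x) for x in range(lo, a + 1))
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= obs * (1 + 1e-7))


def test_fisher_matches_enumeration_oracle_random_tables():
    rng = np.random.default_rng(1)
    for _ in range(200):
        cells = rng.multinomial(int(rng.integers(4, 41)), [0.25] * 4)
        a, b, c, d = (int(x) for x in cells)
        for alt in ("two_sided", "greater", "less"):
            got = ist.fisher_exact([[a, b], [c, d]], alternative=alt).p
            assert got == pytest.approx(fisher_oracle(a, b, c, d, alt), rel=1e-6)


def test_fisher_degenerate_margin():
    res = ist.fisher_exact([[0, 10], [0, 10]])
    assert res.p == 1.0 and res.odds_ratio is None


def test_fisher_row_column_swap_invariance():
    res = ist.fisher_exact([[9, 22], [6, 43]])
    swapped = ist.fisher_exact([[43, 6], [22, 9]])
    assert res.p == pytest.approx(swapped.p, rel=1e-9)
    # OR inverts under a single row swap
    inv = ist.fisher_exact([[6, 43], [9, 22]])
    assert inv.odds_ratio == pytest.approx(1 / res.odds_ratio, rel=1e-6)
    assert inv.ci95[0] == pytest.approx(1 / res.ci95[1], rel=1e-4)


def test_fisher_ci_inverts_conditional_test():
    """At the CI bounds the conditional (noncentral hypergeometric) tail is 2.5%."""
    a, b, c, d = 9, 22, 6, 43
    res = ist.fisher_exact([[a, b], [c, d]])
    n1, n2, ct = a + b, c + d, a + c
    lo, hi = res.ci95
    upper_tail_at_lo = sps.nchypergeom_fisher.sf(a - 1, n1 + n2, n1, ct, lo)
    lower_tail_at_hi = sps.nchypergeom_fisher.cdf(a, n1 + n2, n1, ct, hi)
    assert upper_tail_at_lo == pytest.approx(0.025, abs=2e-3)
    assert lower_tail_at_hi == pytest.approx(0.025, abs=2e-3)


# ---------------------------------------------------------------------------
# Adjusted Mann-Whitney

def test_plain_reduction_no_covariates():
    rng = np.random.default_rng(3)
    y = rng.normal(size=30)
    mask = np.zeros(30, dtype=bool)
    mask[:12] = True
    ours = ist.adjusted_mannwhitney(y, mask, alternative="two_sided")
    ref = sps.mannwhitneyu(y[mask], y[~mask], alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    assert ours.u == ref.statistic and ours.p == ref.pvalue


def test_mirror_symmetric_fixture_u_half():
    y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    mask = np.array([True, False, True, False, True, False])
    res = ist.adjusted_mannwhitney(y, mask, alternative="two_sided")
    # {1,3,5} vs {2,4,6}: U = 3+2+... = count of pairs won
    assert 0 <= res.u <= 9
    res_sym = ist.adjusted_mannwhitney(
        np.array([1, 2, 3, 4]), np.array([True, False, False, True]),
        alternative="two_sided")
    assert res_sym.u == 2.0   # n1*n2/2 for the mirror-symmetric fixture


def test_full_separation_maximal_u():
    y = np.concatenate([np.ones(5) + np.arange(5), -np.arange(6, dtype=float)])
    mask = np.array([True] * 5 + [False] * 6)
    res = ist.adjusted_mannwhitney(y, mask, alternative="greater")
    assert res.u == 30.0
    assert res.p < 0.01


def test_small_sample_close_to_exact_permutation():
    rng = np.random.default_rng(8)
    for _ in range(10):
        n1, n2 = 5, 6
        y = rng.normal(size=n1 + n2)
        mask = np.zeros(n1 + n2, dtype=bool)
        mask[:n1] = True
        res = ist.adjusted_mannwhitney(y, mask, alternative="greater")
        # exact permutation distribution of U
        obs_u = res.u
        count = total = 0
        for comb in itertools.combinations(range(n1 + n2), n1):
            m = np.zeros(n1 + n2, dtype=bool)
            m[list(comb)] = True
            u = sps.mannwhitneyu(y[m], y[~m], alternative="greater",
                                 method="asymptotic").statistic
            count += u >= obs_u
            total += 1
        assert res.p == pytest.approx(count / total, abs=0.02)


def test_confound_only_fixture_adjustment_removes_effect():
    """Group difference fully explained by a covariate: adjusted test is null."""
    rng = np.random.default_rng(42)
    n = 60
    n_sig_unadj = n_nonsig_adj = 0
    reps = 200
    for _ in range(reps):
        mask = np.zeros(n, dtype=bool)
        mask[: n // 2] = True
        cov = mask + rng.normal(scale=0.3, size=n)
        y = 2.0 * cov + rng.normal(scale=0.3, size=n)
        p_unadj = ist.adjusted_mannwhitney(y, mask, alternative="two_sided").p
        p_adj = ist.adjusted_mannwhitney(y, mask, covariates=cov[:, None],
                                         alternative="two_sided").p
        n_sig_unadj += p_unadj < 0.05
        n_nonsig_adj += p_adj > 0.05
    assert n_sig_unadj >= 0.9 * reps
    assert n_nonsig_adj >= 0.9 * reps


def test_empty_group_errors():
    with pytest.raises(ValueError):
        ist.adjusted_mannwhitney(np.ones(5), np.ones(5, dtype=bool))


# ---------------------------------------------------------------------------
# GWAS chi-square

def test_gwas_full_separation_closed_form():
    # all ALT in cases, all REF in controls: allelic chi2 = 2 * n_samples
    n1, n2 = 7, 9
    g = np.array([[2]] * n1 + [[0]] * n2, dtype=np.int8)
    gm = make_gm(g)
    mask = np.array([True] * n1 + [False] * n2)
    res = ist.gwas_single_variant(gm, mask, model="allelic")
    assert res.at[0, "chi2"] == pytest.approx(2 * (n1 + n2))


def test_gwas_monomorphic_p_one():
    gm = make_gm(np.zeros((10, 1), dtype=np.int8))
    mask = np.zeros(10, dtype=bool)
    mask[:4] = True
    for model in ("allelic", "dominant", "recessive"):
        assert ist.gwas_single_variant(gm, mask, model=model).at[0, "p"] == 1.0


def test_gwas_null_pvalues_roughly_uniform():
    rng = np.random.default_rng(17)
    n, m = 300, 5000
    maf = rng.uniform(0.2, 0.5, size=m)
    g = rng.binomial(2, maf, size=(n, m)).astype(np.int8)
    gm = make_gm(g)
    mask = np.zeros(n, dtype=bool)
    mask[:150] = True
    p = ist.gwas_single_variant(gm, mask, model="allelic")["p"].to_numpy()
    # the statistic is discrete, so tail calibration (not the full CDF) is
    # the meaningful uniformity check: rejection rates near nominal levels
    for alpha in (0.01, 0.05, 0.10):
        rate = float((p < alpha).mean())
        se = np.sqrt(alpha * (1 - alpha) / m)
        assert abs(rate - alpha) < 3 * se + 1e-12


def test_gwas_dominant_recessive_tables():
    g = np.array([[2], [1], [1], [0], [0], [0]], dtype=np.int8)
    gm = make_gm(g)
    mask = np.array([True, True, True, False, False, False])
    dom = ist.gwas_single_variant(gm, mask, model="dominant")
    rec = ist.gwas_single_variant(gm, mask, model="recessive")
    # dominant carriers: 3 vs 0 ; recessive carriers: 1 vs 0
    exp = float(sps.chi2.sf(6.0, 1))
    assert dom.at[0, "p"] == pytest.approx(exp)
    # recessive table [[1,2],[0,3]]: chi2 = n(ad-bc)^2/(r1 r2 c1 c2)
    assert rec.at[0, "chi2"] == pytest.approx(6 * (1 * 3 - 2 * 0) ** 2 / (3 * 3 * 1 * 5))


# ---------------------------------------------------------------------------
# Collapsing test, Bonferroni, plot tables

def test_bonferroni_values():
    assert ist.bonferroni(0.003, 12) == pytest.approx(0.036)
    assert ist.bonferroni(0.5, 12) == 1.0
    assert ist.bonferroni(0.123, 1) == pytest.approx(0.123)


def test_collapsing_carrier_delegates_to_fisher(small_cohort):
    table = small_cohort.variants
    roles = small_cohort.samples.set_index("sample_id")["role"]
    mask = np.array([roles[s] == "case" for s in table.samples])
    gene = table.variants["gene"].iloc[0]
    res = ist.collapsing_carrier_test(table, gene, mask)
    # recompute the same 2x2 by hand
    af = table.cohort_allele_frequency()
    qual = (table.variants["gene"] == gene).to_numpy() & (af >= 1e-6) & (af <= 0.05)
    carrier = (table.gt[qual, :] > 0).any(axis=0)
    expected = ist.fisher_exact(
        [[int(carrier[mask].sum()), int(mask.sum() - carrier[mask].sum())],
         [int(carrier[~mask].sum()), int((~mask).sum() - carrier[~mask].sum())]],
        alternative="greater")
    assert res.p == expected.p


def test_no_carriers_p_one(small_cohort):
    table = small_cohort.variants
    mask = np.zeros(len(table.samples), dtype=bool)
    mask[:5] = True
    res = ist.collapsing_carrier_test(table, "NOT_A_GENE", mask)
    assert res.p == 1.0


def test_manhattan_qq_tables():
    p = np.array([1.0])
    man, qq = ist.manhattan_qq_tables(p)
    assert man["neg_log10_p"].iloc[0] == 0.0
    with pytest.raises(ValueError):
        ist.manhattan_qq_tables(np.array([]))
    rng = np.random.default_rng(2)
    pu = rng.uniform(size=2000)
    _, qq = ist.manhattan_qq_tables(pu)
    slope = np.polyfit(qq["expected"], qq["observed"], 1)[0]
    assert slope == pytest.approx(1.0, abs=0.1)
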