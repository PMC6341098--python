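"""Synthetic isolate-cohort generator.

Emulates the design of a small founder-population case-control study:
case families whose parents are (with configurable probability) second
cousins, sibling and parent samples, an unrelated-or-consanguineous
control group, pedigree-transmitted genotypes with Haldane-style
independent crossovers (so multi-megabase autozygous tracts arise only
through pedigree loops), rare annotated SNVs/indels with a planted excess
of homozygous deleterious genotypes in cases, rare exonic CNV calls
enriched in designated gene sets, and external GWAS summary statistics
under which cases carry a higher polygenic score.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    MISSING,
    AnnotatedVariantTable,
    GeneSetCollection,
    GenotypeMatrix,
    MarkerMap,
    Pedigree,
    make_cnv_table,
    make_sample_table,
    make_summary_stats,
)


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the emulated study: 36 case families (one affected
    child each, one genotyped sibling), 185 controls, elevated
    consanguinity among case parents (second-cousin loops), rare-variant
    gnomAD frequencies spanning the 1% / 5% filter boundaries, and a
    polygenic signal that shifts cases upward.
    """

    seed: int = 0
    # cohort layout
    n_case_families: int = 36
    n_sibling_per_family: int = 1
    n_control_samples: int = 185
    case_second_cousin_fraction: float = 0.6
    control_second_cousin_fraction: float = 0.25
    prob_case_has_id: float = 0.4
    # marker map / gene dropping
    n_chromosomes: int = 6
    n_markers_per_chromosome: int = 1000
    chromosome_length_bp: int = 100_000_000
    founder_maf_low: float = 0.05
    founder_maf_high: float = 0.5
    recombination_prob: float = 0.001   # per adjacent-marker interval (~1 Morgan/chr)
    missing_rate: float = 0.002
    # gene universe and sets
    n_genes: int = 400
    geneset_sizes: dict = field(default_factory=lambda: {"SFARI": 60, "PLI09": 80, "BRAIN": 100})
    # rare-variant plan
    n_lgd: int = 120
    n_mis30: int = 120
    n_other: int = 260
    maf_log10_low: float = -5.0          # gnomAD MAF log-uniform on [1e-5, 5e-2]
    maf_log10_high: float = np.log10(0.05)
    lambda_hom_control: float = 0.5      # mean homozygous deleterious load, controls
    delta_hom: float = 0.5               # planted case excess (>= 0)
    geneset_enrichment: float = 0.5      # prob a planted case hit lands in the set union
    background_het_rate_scale: float = 2.0
    # CNV plan
    cnv_set_carrier_probs: dict = field(
        default_factory=lambda: {"SFARI": (0.18, 0.06)}  # set -> (p_case, p_control)
    )
    cnv_background_rate: float = 0.3     # expected background calls per sample, any gene
    cnv_noise_rate: float = 0.15         # calls designed to fail the QC cascade
    # polygenic plan
    n_causal_markers: int = 30
    causal_beta_mean: float = 0.25
    causal_beta_sd: float = 0.08
    liability_shift: float = 1.0         # scales the case allele-frequency shift

    def __post_init__(self) -> None:
        for name in ("case_second_cousin_fraction", "control_second_cousin_fraction",
                     "missing_rate", "geneset_enrichment", "recombination_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.delta_hom < 0:
            raise ValueError("delta_hom must be >= 0")
        for _, (pc, pn) in self.cnv_set_carrier_probs.items():
            if not (0 <= pc <= 1 and 0 <= pn <= 1):
                raise ValueError("CNV carrier probabilities must be in [0, 1]")


# ---------------------------------------------------------------------------
# Pedigrees

def _second_cousin_parents(fam: str, members: dict, rows: list) -> tuple[str, str]:
    """Add a second-cousin parental loop to ``members``; return the parent pair.

    The two parents share one great-grandparental founder couple; all other
    ancestors are unrelated founders, so kinship(parent1, parent2) = 1/64.
    """
    def add(sid, fa, mo, sex, role="parent"):
        members[sid] = (fa, mo)
        rows.append(dict(sample_id=sid, family_id=fam, father_id=fa or "",
                         mother_id=mo or "", sex=sex, role=role))
        return sid

    gg_f = add(f"{fam}_GGF", None, None, "male")
    gg_m = add(f"{fam}_GGM", None, None, "female")
    p = {}
    for side in ("a", "b"):
        child = add(f"{fam}_C{side}", gg_f, gg_m, "male" if side == "a" else "female")
        sp1 = add(f"{fam}_S{side}1", None, None, "female" if side == "a" else "male")
        gchild = add(f"{fam}_D{side}", child if side == "a" else sp1,
                     sp1 if side == "a" else child, "male" if side == "a" else "female")
        sp2 = add(f"{fam}_S{side}2", None, None, "female" if side == "a" else "male")
        p[side] = add(f"{fam}_P{side}", gchild if side == "a" else sp2,
                      sp2 if side == "a" else gchild, "male" if side == "a" else "female")
    return p["a"], p["b"]


def _founder_parents(fam: str, members: dict, rows: list) -> tuple[str, str]:
    for sid, sex in ((f"{fam}_Pa", "male"), (f"{fam}_Pb", "female")):
        members[sid] = (None, None)
        rows.append(dict(sample_id=sid, family_id=fam, father_id="", mother_id="",
                         sex=sex, role="parent"))
    return f"{fam}_Pa", f"{fam}_Pb"


def generate_pedigrees(config: SimConfig, rng: np.random.Generator | None = None
                       ) -> tuple[Pedigree, pd.DataFrame]:
    """Build the cohort pedigree and sample table.

    Case families hold one affected child plus ``n_sibling_per_family``
    siblings; each family's parents are second cousins with probability
    ``case_second_cousin_fraction`` (controls: their own fraction).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    members: dict[str, tuple[str | None, str | None]] = {}
    rows: list[dict] = []

    for k in range(config.n_case_families):
        fam = f"FAM{k:04d}"
        consang = rng.random() < config.case_second_cousin_fraction
        fa, mo = (_second_cousin_parents(fam, members, rows) if consang
                  else _founder_parents(fam, members, rows))
        children = [(f"{fam}_A1", "case", bool(rng.random() < config.prob_case_has_id))]
        children += [(f"{fam}_S{j + 1}", "sibling", False)
                     for j in range(config.n_sibling_per_family)]
        for sid, role, has_id in children:
            members[sid] = (fa, mo)
            rows.append(dict(sample_id=sid, family_id=fam, father_id=fa, mother_id=mo,
                             sex="male" if rng.random() < 0.5 else "female",
                             role=role, has_id=has_id))

    for k in range(config.n_control_samples):
        fam = f"CTL{k:04d}"
        consang = rng.random() < config.control_second_cousin_fraction
        fa, mo = (_second_cousin_parents(fam, members, rows) if consang
                  else _founder_parents(fam, members, rows))
        sid = f"{fam}_A1"
        members[sid] = (fa, mo)
        rows.append(dict(sample_id=sid, family_id=fam, father_id=fa, mother_id=mo,
                         sex="male" if rng.random() < 0.5 else "female", role="control"))

    samples = make_sample_table(pd.DataFrame(rows))
    return Pedigree(members), samples


# ---------------------------------------------------------------------------
# Gene dropping

def default_marker_map(config: SimConfig) -> MarkerMap:
    rows = []
    for c in range(1, config.n_chromosomes + 1):
        m = config.n_markers_per_chromosome
        pos = np.linspace(1, config.chromosome_length_bp, m).astype(np.int64)
        pos = np.maximum.accumulate(pos + np.arange(m))  # strictly increasing
        for j in range(m):
            rows.append(dict(marker_id=f"rs{c}_{j}", chrom=str(c), pos=int(pos[j]),
                             allele_a="A", allele_b="B"))
    return MarkerMap(pd.DataFrame(rows))


def drop_genotypes(
    pedigree: Pedigree,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    markers: MarkerMap | None = None,
    founder_freqs: np.ndarray | None = None,
    return_haplotypes: bool = False,
):
    """Gene-drop genotypes through the pedigree.

    Founder haplotypes are Bernoulli draws from per-marker allele
    frequencies; each transmitted gamete recombines between adjacent
    markers independently with ``recombination_prob`` (Haldane model, no
    interference).  Autozygosity — and hence ROH — arises only through
    pedigree loops.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    markers = markers if markers is not None else default_marker_map(config)
    m = len(markers)
    freqs = (founder_freqs if founder_freqs is not None
             else rng.uniform(config.founder_maf_low, config.founder_maf_high, size=m))
    chroms = markers.chroms
    chrom_start = np.zeros(m, dtype=bool)
    chrom_start[0] = True
    chrom_start[1:] = chroms[1:] != chroms[:-1]

    haplos: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def gamete(parent: str) -> np.ndarray:
        h1, h2 = haplos[parent]
        switch = rng.random(m) < config.recombination_prob
        # a fresh random phase at each chromosome start decouples chromosomes
        switch[chrom_start] = rng.random(int(chrom_start.sum())) < 0.5
        state = np.cumsum(switch) % 2
        return np.where(state == 0, h1, h2)

    for ind in pedigree.topological_order():
        fa, mo = pedigree.members[ind]
        if fa is None or mo is None:
            haplos[ind] = (
                (rng.random(m) < freqs).astype(np.int8),
                (rng.random(m) < freqs).astype(np.int8),
            )
        else:
            haplos[ind] = (gamete(fa), gamete(mo))

    samples = list(pedigree.members)
    geno = np.empty((len(samples), m), dtype=np.int8)
    for i, s in enumerate(samples):
        geno[i] = haplos[s][0] + haplos[s][1]
    if config.missing_rate > 0:
        mask = rng.random(geno.shape) < config.missing_rate
        geno[mask] = MISSING
    gm = GenotypeMatrix(samples, markers, geno)
    return (gm, haplos) if return_haplotypes else gm


# ---------------------------------------------------------------------------
# Gene universe and sets

def make_gene_universe(config: SimConfig, rng: np.random.Generator
                       ) -> tuple[pd.DataFrame, GeneSetCollection]:
    """Lay genes along the chromosomes and draw the named gene sets.

    Genes are 50 kb single-exon intervals spaced 200 kb apart; set
    membership is a random draw without replacement (sets may overlap each
    other since they are drawn independently).
    """
    names = [f"G{i:04d}" for i in range(config.n_genes)]
    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    rows = []
    for i, g in enumerate(names):
        c = i // per_chrom + 1
        k = i % per_chrom
        start = 500_000 + k * 250_000
        rows.append(dict(gene=g, chrom=str(c), start=start, end=start + 50_000))
    genes = pd.DataFrame(rows)
    sets = {}
    for set_name, size in config.geneset_sizes.items():
        size = min(size, config.n_genes)
        sets[set_name] = frozenset(rng.choice(names, size=size, replace=False).tolist())
    return genes, GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# Rare variants

_LGD_CONSEQUENCES = ("stopgain", "splice_site", "frameshift")


def plant_rare_variants(
    samples: pd.DataFrame,
    genes: pd.DataFrame,
    gene_sets: GeneSetCollection,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> AnnotatedVariantTable:
    """Generate annotated rare variants with a planted homozygous excess in cases.

    Consequence labels and CADD scores are drawn so downstream
    classification yields the configured LGD / MIS30 / other counts.
    Each case receives Poisson(lambda + delta_hom) qualifying homozygous
    genotypes; every other cohort member receives Poisson(lambda).
    Planted hits land in the gene-set union with probability
    ``geneset_enrichment``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_var = config.n_lgd + config.n_mis30 + config.n_other
    gene_names = genes["gene"].to_numpy()
    gene_idx = rng.integers(0, len(gene_names), size=n_var)
    rows = []
    for v in range(n_var):
        g = genes.iloc[gene_idx[v]]
        if v < config.n_lgd:
            csq = _LGD_CONSEQUENCES[rng.integers(0, 3)]
            cadd = float(rng.uniform(10, 50))
        elif v < config.n_lgd + config.n_mis30:
            csq = "missense"
            cadd = float(rng.uniform(30, 60))
        else:
            csq = "missense" if rng.random() < 0.5 else "synonymous"
            cadd = float(rng.uniform(0, 29.5))
        maf = float(10 ** rng.uniform(config.maf_log10_low, config.maf_log10_high))
        ref, alt = ("A", "T") if rng.random() < 0.5 else ("C", "G")
        rows.append(dict(chrom=g["chrom"], pos=int(g["start"]) + int(rng.integers(0, 50_000)),
                         ref=ref, alt=alt, gene=g["gene"], consequence=csq,
                         cadd=cadd, gnomad_maf=maf))
    variants = pd.DataFrame(rows)

    sample_ids = samples["sample_id"].tolist()
    n_s = len(sample_ids)
    gt = np.zeros((n_var, n_s), dtype=np.int8)
    # background heterozygous carriers at roughly the gnomAD frequency
    het_p = np.clip(config.background_het_rate_scale * variants["gnomad_maf"].to_numpy(), 0, 0.5)
    gt[rng.random((n_var, n_s)) < het_p[:, None]] = 1

    cls = np.where(np.isin(variants["consequence"], _LGD_CONSEQUENCES), "LGD",
                   np.where((variants["consequence"] == "missense") & (variants["cadd"] >= 30),
                            "MIS30", "OTHER"))
    qualifying = np.flatnonzero((cls != "OTHER") & (variants["gnomad_maf"] < 0.01))
    if qualifying.size == 0:
        raise ValueError("rare-variant plan produced no qualifying deleterious variants")
    union = gene_sets.union()
    in_union = np.isin(variants["gene"].str.upper().to_numpy(), sorted(union))
    q_in = qualifying[in_union[qualifying]]
    q_out = qualifying[~in_union[qualifying]]

    roles = samples.set_index("sample_id")["role"]
    for i, sid in enumerate(sample_ids):
        lam = config.lambda_hom_control + (config.delta_hom if roles[sid] == "case" else 0.0)
        k = int(rng.poisson(lam))
        for _ in range(k):
            pool = q_in if (q_in.size and rng.random() < config.geneset_enrichment) else \
                (q_out if q_out.size else q_in)
            gt[int(pool[rng.integers(0, len(pool))]), i] = 2

    gq = rng.uniform(40, 99, size=gt.shape)
    dp = rng.integers(15, 60, size=gt.shape).astype(np.int32)
    return AnnotatedVariantTable(variants, sample_ids, gt, gq, dp)


# ---------------------------------------------------------------------------
# CNVs

def plant_cnvs(
    samples: pd.DataFrame,
    genes: pd.DataFrame,
    gene_sets: GeneSetCollection,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate rare exonic CNV calls with per-group, per-set carrier probabilities.

    Planted and background calls are built to pass the WES QC cascade
    (QSOME >= 90, >= 5 targets, low segdup overlap); an extra
    ``cnv_noise_rate`` of calls is built to fail it, exercising the filter.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    gene_by_name = genes.set_index("gene")
    rows = []

    def add_call(sid: str, gene: str, passing: bool) -> None:
        g = gene_by_name.loc[gene]
        pad = int(rng.integers(0, 20_000))
        rows.append(dict(
            sample_id=sid, chrom=g["chrom"],
            start=max(1, int(g["start"]) - pad), end=int(g["end"]) + int(rng.integers(0, 20_000)),
            type="deletion" if rng.random() < 0.5 else "duplication",
            source="wes",
            confidence=float(rng.uniform(90, 99)) if passing else float(rng.uniform(10, 89)),
            n_probes_or_targets=int(rng.integers(5, 15)) if passing else int(rng.integers(1, 5)),
            segdup_overlap_fraction=float(rng.uniform(0, 0.4)) if passing
            else float(rng.uniform(0.51, 1.0)),
        ))

    cohort = samples[samples["role"].isin(("case", "control", "sibling"))]
    for _, row in cohort.iterrows():
        sid, role = row["sample_id"], row["role"]
        for set_name, (p_case, p_ctrl) in config.cnv_set_carrier_probs.items():
            p = p_case if role == "case" else p_ctrl
            if rng.random() < p:
                members = sorted(gene_sets[set_name])
                add_call(sid, members[rng.integers(0, len(members))], passing=True)
        for _ in range(rng.poisson(config.cnv_background_rate)):
            add_call(sid, genes["gene"].iloc[rng.integers(0, len(genes))], passing=True)
        for _ in range(rng.poisson(config.cnv_noise_rate)):
            add_call(sid, genes["gene"].iloc[rng.integers(0, len(genes))], passing=False)
    if not rows:
        return make_cnv_table(pd.DataFrame(columns=["sample_id", "chrom", "start", "end",
                                                    "type", "source", "confidence",
                                                    "n_probes_or_targets",
                                                    "segdup_overlap_fraction"]))
    return make_cnv_table(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# GWAS summary statistics and polygenic signal

def make_gwas_summary(markers: MarkerMap, config: SimConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Summary statistics: causal markers with beta > 0 and small p, rest null."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    m = len(markers)
    n_causal = min(config.n_causal_markers, m)
    causal = np.zeros(m, dtype=bool)
    causal[rng.choice(m, size=n_causal, replace=False)] = True
    beta = np.zeros(m)
    beta[causal] = np.abs(rng.normal(config.causal_beta_mean, config.causal_beta_sd,
                                     size=n_causal))
    p = rng.uniform(0.0, 1.0, size=m)
    p[p == 0] = 0.5
    p[causal] = 10 ** rng.uniform(-6, -2, size=n_causal)
    return make_summary_stats(pd.DataFrame(dict(
        marker_id=markers.marker_ids, effect_allele=markers.table["allele_b"],
        beta=beta, p=p,
    )))


def plant_polygenic_signal(
    gm: GenotypeMatrix,
    samples: pd.DataFrame,
    summary: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Redraw genotypes at causal markers with a case-specific frequency shift.

    The shift is proportional to the causal beta (scaled by
    ``liability_shift``), so under all-positive betas cases end up with a
    higher polygenic score.  Transmission at these markers is redrawn
    under Hardy-Weinberg per group, independently of the pedigree.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    causal = summary.loc[summary["beta"] != 0]
    ids = list(gm.markers.marker_ids)
    case_ids = set(samples.loc[samples["role"] == "case", "sample_id"])
    is_case = np.array([s in case_ids for s in gm.samples])
    geno = gm.genotypes.copy()
    for _, row in causal.iterrows():
        if row["marker_id"] not in ids:
            continue
        j = ids.index(row["marker_id"])
        called = geno[:, j] != MISSING
        base_f = float(np.clip(np.where(called, geno[:, j], 0).sum()
                               / max(2 * called.sum(), 1), 0.05, 0.95))
        shift = config.liability_shift * row["beta"] * base_f * (1 - base_f) * 2.0
        f = np.where(is_case, np.clip(base_f + shift, 0.01, 0.99), base_f)
        draws = (rng.random(gm.n_samples) < f).astype(np.int8) + \
                (rng.random(gm.n_samples) < f).astype(np.int8)
        geno[called, j] = draws[called]
    return GenotypeMatrix(list(gm.samples), gm.markers, geno)


# ---------------------------------------------------------------------------
# Full cohort

@dataclass
class SyntheticCohort:
    config: SimConfig
    pedigree: Pedigree
    samples: pd.DataFrame
    genotypes: GenotypeMatrix
    variants: AnnotatedVariantTable
    cnvs: pd.DataFrame
    genes: pd.DataFrame
    gene_sets: GeneSetCollection
    summary_stats: pd.DataFrame


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort deterministically from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    pedigree, samples = generate_pedigrees(config, rng)
    gm = drop_genotypes(pedigree, config, rng)
    genes, gene_sets = make_gene_universe(config, rng)
    variants = plant_rare_variants(samples, genes, gene_sets, config, rng)
    cnvs = plant_cnvs(samples, genes, gene_sets, config, rng)
    summary = make_gwas_summary(gm.markers, config, rng)
    gm = plant_polygenic_signal(gm, samples, summary, config, rng)
    return SyntheticCohort(config, pedigree, samples, gm, variants, cnvs, genes,
                           gene_sets, summary)
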