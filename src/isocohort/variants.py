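"""Rare-variant classification, filtering, de novo detection and load counting.

Variant classes follow the standard exome prioritization scheme: likely
gene-disruptive (LGD = stopgain, splice-site, frameshift), MIS30
(missense with CADD >= 30), and OTHER.  The homozygous deleterious load
of a sample counts its qualifying rare (gnomAD MAF < 1%) LGD/MIS30
homozygous-alternate genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MISSING, AnnotatedVariantTable
from .popstruct import hwe_exact_test
from .stats import fisher_exact, FisherResult

logger = logging.getLogger("isocohort")

LGD_CONSEQUENCES = ("stopgain", "splice_site", "frameshift")
KNOWN_CONSEQUENCES = LGD_CONSEQUENCES + ("missense", "synonymous", "other")


def classify_variant(consequence: str, cadd: float | None = None) -> str:
    """Classify one variant as ``LGD``, ``MIS30`` or ``OTHER``.

    Stopgain/splice-site/frameshift are LGD regardless of CADD; missense
    with CADD >= 30 is MIS30; everything else (including unknown labels,
    with a warning) is OTHER.
    """
    if consequence in LGD_CONSEQUENCES:
        return "LGD"
    if consequence not in KNOWN_CONSEQUENCES:
        logger.warning("classify_variant: unknown consequence %r -> OTHER", consequence)
        return "OTHER"
    if consequence == "missense" and cadd is not None and cadd >= 30:
        return "MIS30"
    return "OTHER"


def classify_table(table: AnnotatedVariantTable) -> np.ndarray:
    """Vectorized classification of every record in the table."""
    csq = table.variants["consequence"].to_numpy()
    cadd = table.variants["cadd"].to_numpy()
    return np.array([classify_variant(c, x) for c, x in zip(csq, cadd)])


@dataclass
class RarityFilter:
    """QC and rarity thresholds for the homozygous-load / burden analyses.

    Application order (fixed, reported): site-level QC (biallelic records
    are assumed by construction; missingness, HWE), genotype-level masking
    (GQ, DP), then frequency filters (gnomAD MAF and internal control
    allele frequency).
    """

    max_gnomad_maf: float = 0.01        # 1% for the homozygous analysis; 5% for burden
    max_internal_control_freq: float = 0.15
    genotype_quality_min: float = 30.0
    depth_min: int = 10
    max_missing_fraction: float = 0.10
    hwe_p_min: float = 1e-6
    keep_missing_gnomad: bool = True    # variants absent from gnomAD pass the MAF rule


def apply_rarity_filter(
    table: AnnotatedVariantTable,
    filt: RarityFilter,
    control_mask: np.ndarray,
) -> tuple[AnnotatedVariantTable, dict]:
    """Apply the QC + rarity cascade; returns filtered table and a report.

    ``control_mask`` flags the control samples used for the internal
    allele-frequency filter.  Genotypes failing GQ/DP are masked to
    missing before any frequency is computed.
    """
    control_mask = np.asarray(control_mask, dtype=bool)
    report: dict[str, int] = {"n_input": table.n_variants}

    # genotype-level masking first so site metrics see clean calls
    gt = table.gt.copy()
    bad_gt = (table.gq < filt.genotype_quality_min) | (table.dp < filt.depth_min)
    n_masked = int((bad_gt & (gt != MISSING)).sum())
    gt[bad_gt] = MISSING
    report["genotypes_masked"] = n_masked
    masked = AnnotatedVariantTable(table.variants, table.samples, gt, table.gq, table.dp)

    keep = np.ones(table.n_variants, dtype=bool)

    miss_frac = (gt == MISSING).mean(axis=1)
    fail = miss_frac > filt.max_missing_fraction
    report["missingness"] = int((keep & fail).sum())
    keep &= ~fail

    hwe_p = np.ones(table.n_variants)
    for j in range(table.n_variants):
        col = gt[j, :]
        n0, n1, n2 = int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        if n0 + n1 + n2 > 0:
            hwe_p[j] = hwe_exact_test(n0, n1, n2)
    fail = hwe_p < filt.hwe_p_min
    report["hwe"] = int((keep & fail).sum())
    keep &= ~fail

    gmaf = table.variants["gnomad_maf"].to_numpy(dtype=float)
    nan_stand_in = -1.0 if filt.keep_missing_gnomad else 1.0
    fail = np.nan_to_num(gmaf, nan=nan_stand_in) > filt.max_gnomad_maf
    report["gnomad_maf"] = int((keep & fail).sum())
    keep &= ~fail

    ctrl_gt = gt[:, control_mask]
    called = ctrl_gt != MISSING
    with np.errstate(invalid="ignore"):
        ctrl_af = np.where(called.sum(axis=1) > 0,
                           np.where(called, ctrl_gt, 0).sum(axis=1)
                           / np.maximum(2 * called.sum(axis=1), 1), 0.0)
    fail = ctrl_af > filt.max_internal_control_freq
    report["internal_control_freq"] = int((keep & fail).sum())
    keep &= ~fail

    report["n_kept"] = int(keep.sum())
    return masked.subset_variants(keep), report


# ---------------------------------------------------------------------------
# De novo detection

@dataclass
class DenovoCall:
    child_id: str
    variant_index: int
    chrom: str
    pos: int
    gene: str
    child_gt: int


def detect_denovo(
    table: AnnotatedVariantTable,
    trios: list[tuple[str, str, str]],
    count_hom_alt: bool = True,
) -> tuple[list[DenovoCall], dict]:
    """Detect de novo variants in (child, father, mother) trios.

    A call is de novo when the child carries >= 1 ALT allele and both
    parents are called homozygous reference.  Sites where either parent is
    missing are skipped and counted.  ``count_hom_alt`` controls whether a
    hom-alt child of double hom-ref parents is counted (genotyping-error
    prone but rule-consistent).
    """
    idx = {s: i for i, s in enumerate(table.samples)}
    calls: list[DenovoCall] = []
    n_skipped = 0
    for child, father, mother in trios:
        ci, fi, mi = idx[child], idx[father], idx[mother]
        for j in range(table.n_variants):
            c, f, m = table.gt[j, ci], table.gt[j, fi], table.gt[j, mi]
            if c == MISSING:
                continue
            if f == MISSING or m == MISSING:
                if c > 0:
                    n_skipped += 1
                continue
            if c > 0 and f == 0 and m == 0:
                if c == 2 and not count_hom_alt:
                    continue
                v = table.variants.iloc[j]
                calls.append(DenovoCall(child, j, v["chrom"], int(v["pos"]),
                                        v["gene"], int(c)))
    return calls, {"skipped_sites": n_skipped}


def denovo_rate(calls: list[DenovoCall], samples: pd.DataFrame) -> pd.Series:
    """Mean de novo events per individual, by role (individuals with zero
    events included in the denominator)."""
    counts = pd.Series([c.child_id for c in calls]).value_counts()
    per_sample = samples.set_index("sample_id")["role"].to_frame()
    per_sample["n"] = counts.reindex(per_sample.index).fillna(0)
    return per_sample.groupby("role")["n"].mean()


# ---------------------------------------------------------------------------
# Homozygous deleterious load

@dataclass
class LoadProfile:
    sample_id: str
    n_hom_deleterious: int
    genes_hit: frozenset[str]
    set_hits: dict = field(default_factory=dict)

    @property
    def n_genes_hit(self) -> int:
        return len(self.genes_hit)


def homozygous_load(
    table: AnnotatedVariantTable,
    sample: str,
    classes: tuple[str, ...] = ("LGD", "MIS30"),
    gene_sets=None,
) -> LoadProfile:
    """Count qualifying homozygous-ALT genotypes for one sample.

    ``table`` should already be rarity-filtered (MAF < 1% cascade).  Both
    the per-variant count and the distinct-gene count are available on the
    returned profile.
    """
    i = table.samples.index(sample)
    cls = classify_table(table)
    hom = (table.gt[:, i] == 2) & np.isin(cls, classes)
    genes = frozenset(table.variants.loc[hom, "gene"].str.upper())
    set_hits = {}
    if gene_sets is not None:
        for name in gene_sets.names():
            set_hits[name] = bool(genes & gene_sets[name])
    return LoadProfile(sample, int(hom.sum()), genes, set_hits)


def load_profiles(table: AnnotatedVariantTable, samples: list[str] | None = None,
                  gene_sets=None) -> list[LoadProfile]:
    return [homozygous_load(table, s, gene_sets=gene_sets)
            for s in (samples if samples is not None else table.samples)]


def gene_set_hit_test(
    profiles_group1: list[LoadProfile],
    profiles_group2: list[LoadProfile],
    gene_sets,
    set_names: list[str] | None = None,
    alternative: str = "greater",
) -> tuple[pd.DataFrame, FisherResult]:
    """Compare carrier proportions for the union of the named gene sets.

    A carrier is an individual whose hit genes intersect the union;
    Fisher's one-sided test (group1 enriched) on the carrier counts.
    """
    union = gene_sets.union(set_names)
    c1 = sum(1 for p in profiles_group1 if p.genes_hit & union)
    c2 = sum(1 for p in profiles_group2 if p.genes_hit & union)
    n1, n2 = len(profiles_group1), len(profiles_group2)
    res = fisher_exact([[c1, n1 - c1], [c2, n2 - c2]], alternative=alternative)
    summary = pd.DataFrame(dict(
        group=["group1", "group2"], n=[n1, n2], carriers=[c1, c2],
        proportion=[c1 / n1 if n1 else np.nan, c2 / n2 if n2 else np.nan],
    ))
    return summary, res
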