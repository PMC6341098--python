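"""Shared data model for the cohort analysis pipeline.

Conventions used throughout the package:

* genotypes are coded as the dosage of ``allele_b`` (the ALT allele in VCF
  terms): 0, 1, 2, with :data:`MISSING` (= -1) as the single reserved
  missing-data sentinel.  No operation imputes silently.
* genomic coordinates are 1-based inclusive internally; BED I/O converts.
* chromosome labels are normalized by stripping a leading ``chr``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Reserved sentinel for a missing genotype call.
MISSING: int = -1

AUTOSOMES = tuple(str(c) for c in range(1, 23))

CONSEQUENCES = ("stopgain", "splice_site", "frameshift", "missense", "synonymous", "other")

ROLES = ("case", "control", "sibling", "parent")


def normalize_chrom(label: str) -> str:
    """Strip a leading ``chr`` prefix and return the bare chromosome label."""
    s = str(label)
    return s[3:] if s.lower().startswith("chr") else s


@dataclass
class MarkerMap:
    """Ordered map of biallelic markers.

    Backed by a DataFrame with columns ``marker_id``, ``chrom``,
    ``pos`` (1-based), ``allele_a``, ``allele_b``.  Positions must be
    strictly increasing within each chromosome and marker ids unique.
    """

    table: pd.DataFrame

    REQUIRED = ("marker_id", "chrom", "pos", "allele_a", "allele_b")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"marker map missing columns: {missing}")
        t = self.table.reset_index(drop=True).copy()
        t["chrom"] = t["chrom"].map(normalize_chrom)
        t["pos"] = t["pos"].astype(np.int64)
        if (t["pos"] < 1).any():
            raise ValueError("marker positions must be >= 1 (1-based)")
        if t["marker_id"].duplicated().any():
            dups = t.loc[t["marker_id"].duplicated(), "marker_id"].tolist()
            raise ValueError(f"duplicate marker ids: {dups[:5]}")
        for chrom, grp in t.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError(f"positions not strictly increasing on chromosome {chrom}")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    @property
    def chroms(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.table["pos"].to_numpy()

    def autosomal_mask(self) -> np.ndarray:
        return np.isin(self.chroms, AUTOSOMES)

    def subset(self, mask: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.table.loc[np.asarray(mask)].reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Samples x markers matrix of allele_b dosages (0/1/2, MISSING = -1)."""

    samples: list[str]
    markers: MarkerMap
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=np.int8)
        if g.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"genotype shape {g.shape} != (n_samples={len(self.samples)}, "
                f"n_markers={len(self.markers)})"
            )
        bad = ~np.isin(g, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotypes must be 0/1/2 or MISSING (-1)")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        self.genotypes = g

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of missing calls, in [0, 1]."""
        return (self.genotypes == MISSING).mean(axis=0)

    def call_rate_per_sample(self) -> np.ndarray:
        return 1.0 - (self.genotypes == MISSING).mean(axis=1)

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(list(self.samples), self.markers.subset(mask), self.genotypes[:, mask])

    def subset_samples(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in keep]
        return GenotypeMatrix(list(keep), self.markers, self.genotypes[idx, :])


SAMPLE_COLUMNS = ("sample_id", "family_id", "father_id", "mother_id", "sex", "role", "has_id")


def make_sample_table(records: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a sample/pedigree table.

    Required columns: sample_id, family_id, sex, role; optional father_id,
    mother_id (empty string or "0" = absent), has_id flag and arbitrary
    extra covariate columns.
    """
    t = records.copy().reset_index(drop=True)
    for c in ("sample_id", "family_id", "sex", "role"):
        if c not in t.columns:
            raise ValueError(f"sample table missing column {c}")
    for c in ("father_id", "mother_id"):
        if c not in t.columns:
            t[c] = ""
        t[c] = t[c].fillna("").replace("0", "").astype(str)
    if "has_id" not in t.columns:
        t["has_id"] = False
    with pd.option_context("future.no_silent_downcasting", True):
        t["has_id"] = t["has_id"].fillna(False).astype(bool)
    bad_roles = set(t["role"]) - set(ROLES)
    if bad_roles:
        raise ValueError(f"unknown roles: {sorted(bad_roles)}")
    if t["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in sample table")
    known = set(t["sample_id"])
    for c in ("father_id", "mother_id"):
        refs = set(t[c]) - {""}
        orphans = refs - known
        if orphans:
            raise ValueError(f"{c} references unknown samples: {sorted(orphans)[:5]}")
    return t


@dataclass
class Pedigree:
    """Acyclic pedigree; founders have neither parent.

    ``members`` maps id -> (father_id | None, mother_id | None).
    """

    members: dict[str, tuple[str | None, str | None]]

    def __post_init__(self) -> None:
        for child, (fa, mo) in self.members.items():
            for p in (fa, mo):
                if p is not None and p not in self.members:
                    raise ValueError(f"parent {p} of {child} not in pedigree")
        # cycle check via depth computation
        self._depth: dict[str, int] = {}
        for m in self.members:
            self._depth_of(m, frozenset())

    def _depth_of(self, ind: str, stack: frozenset) -> int:
        if ind in self._depth:
            return self._depth[ind]
        if ind in stack:
            raise ValueError(f"pedigree cycle involving {ind}")
        fa, mo = self.members[ind]
        d = 0 if fa is None and mo is None else 1 + max(
            self._depth_of(p, stack | {ind}) for p in (fa, mo) if p is not None
        )
        self._depth[ind] = d
        return d

    def is_founder(self, ind: str) -> bool:
        fa, mo = self.members[ind]
        return fa is None and mo is None

    def depth(self, ind: str) -> int:
        return self._depth[ind]

    def topological_order(self) -> list[str]:
        """Members ordered parents-before-children."""
        return sorted(self.members, key=lambda m: self._depth[m])

    @classmethod
    def from_sample_table(cls, samples: pd.DataFrame) -> "Pedigree":
        members = {}
        for _, row in samples.iterrows():
            fa = row["father_id"] or None
            mo = row["mother_id"] or None
            members[row["sample_id"]] = (fa, mo)
        return cls(members)


@dataclass
class AnnotatedVariantTable:
    """Rare SNV/indel records with annotations and per-sample genotypes.

    ``variants`` columns: chrom, pos, ref, alt, gene, consequence, cadd,
    gnomad_maf (NaN when absent).  ``gt``/``gq``/``dp`` are
    (n_variants, n_samples) arrays; gt uses the package genotype coding.
    """

    variants: pd.DataFrame
    samples: list[str]
    gt: np.ndarray
    gq: np.ndarray
    dp: np.ndarray

    REQUIRED = ("chrom", "pos", "ref", "alt", "gene", "consequence", "cadd", "gnomad_maf")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        v = self.variants.reset_index(drop=True).copy()
        v["chrom"] = v["chrom"].map(normalize_chrom)
        if (v["ref"] == v["alt"]).any():
            raise ValueError("ref == alt in variant record")
        self.variants = v
        shape = (len(v), len(self.samples))
        self.gt = np.asarray(self.gt, dtype=np.int8)
        self.gq = np.asarray(self.gq, dtype=float)
        self.dp = np.asarray(self.dp, dtype=np.int32)
        for name, arr in (("gt", self.gt), ("gq", self.gq), ("dp", self.dp)):
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != {shape}")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def cohort_allele_frequency(self) -> np.ndarray:
        """ALT allele frequency over non-missing genotypes, per variant."""
        called = self.gt != MISSING
        n_alleles = 2 * called.sum(axis=1)
        alt = np.where(called, self.gt, 0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)

    def subset_variants(self, mask: np.ndarray) -> "AnnotatedVariantTable":
        mask = np.asarray(mask)
        return AnnotatedVariantTable(
            self.variants.loc[mask].reset_index(drop=True),
            list(self.samples),
            self.gt[mask, :],
            self.gq[mask, :],
            self.dp[mask, :],
        )


CNV_COLUMNS = (
    "sample_id", "chrom", "start", "end", "type", "source",
    "confidence", "n_probes_or_targets", "segdup_overlap_fraction",
)

CNV_TYPES = ("deletion", "duplication")
CNV_SOURCES = ("array", "wes")


def make_cnv_table(records: pd.DataFrame) -> pd.DataFrame:
    """Validate a CNV call table (internal 1-based inclusive coordinates)."""
    t = records.copy().reset_index(drop=True)
    for c in CNV_COLUMNS:
        if c not in t.columns:
            raise ValueError(f"CNV table missing column {c}")
    t["chrom"] = t["chrom"].map(normalize_chrom)
    t["start"] = t["start"].astype(np.int64)
    t["end"] = t["end"].astype(np.int64)
    if (t["start"] > t["end"]).any():
        bad = t.index[t["start"] > t["end"]].tolist()
        raise ValueError(f"CNV start > end at rows {bad[:5]}")
    if not set(t["type"]) <= set(CNV_TYPES):
        raise ValueError(f"unknown CNV types: {set(t['type']) - set(CNV_TYPES)}")
    if not set(t["source"]) <= set(CNV_SOURCES):
        raise ValueError(f"unknown CNV sources: {set(t['source']) - set(CNV_SOURCES)}")
    frac = t["segdup_overlap_fraction"].astype(float)
    if ((frac < 0) | (frac > 1)).any():
        raise ValueError("segdup_overlap_fraction outside [0, 1]")
    return t


def cnv_length(table: pd.DataFrame) -> np.ndarray:
    """Length in bp of each call (1-based inclusive: end - start + 1)."""
    return (table["end"] - table["start"] + 1).to_numpy()


@dataclass
class GeneSetCollection:
    """Named gene sets; symbols normalized to upper case."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm = {}
        for name, genes in self.sets.items():
            genes = frozenset(str(g).upper() for g in genes)
            if any(not g for g in genes):
                raise ValueError(f"empty gene symbol in set {name}")
            norm[name] = genes
        self.sets = norm

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def union(self, names: list[str] | None = None) -> frozenset[str]:
        names = names if names is not None else self.names()
        out: frozenset[str] = frozenset()
        for n in names:
            out = out | self.sets[n]
        return out


def make_summary_stats(records: pd.DataFrame) -> pd.DataFrame:
    """Validate GWAS summary statistics (marker_id, effect_allele, beta, p)."""
    t = records.copy().reset_index(drop=True)
    for c in ("marker_id", "effect_allele", "beta", "p"):
        if c not in t.columns:
            raise ValueError(f"summary stats missing column {c}")
    t["beta"] = t["beta"].astype(float)
    t["p"] = t["p"].astype(float)
    bad = (t["p"] <= 0) | (t["p"] > 1)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} summary records with p outside (0, 1]")
    return t
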