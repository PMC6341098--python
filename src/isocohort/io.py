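"""Readers and writers for the exchange formats the pipeline touches.

Formats supported (all plain text):

* VCF (subset: CHROM POS ID REF ALT QUAL FILTER INFO, FORMAT with GT/GQ/DP)
  via :mod:`pysam` — genotype matrices and annotated variant tables.
* PLINK-style text genotypes: ``.ped`` plus a ``.map`` dialect that carries
  two extra columns (allele_a, allele_b) so the ALT-dosage coding is
  unambiguous; without them allele_b defaults to the minor allele.
* BED(+4) for CNV calls (0-based half-open on disk, converted to the
  package's 1-based inclusive coordinates).
* TSV for gene sets, GWAS summary statistics and sample/pedigree tables.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd
import pysam

from .datamodel import (
    MISSING,
    AnnotatedVariantTable,
    GeneSetCollection,
    GenotypeMatrix,
    MarkerMap,
    make_cnv_table,
    make_sample_table,
    make_summary_stats,
    normalize_chrom,
)

logger = logging.getLogger("isocohort")


class ParseError(ValueError):
    """Raised when an input file does not parse under the named dialect."""


# ---------------------------------------------------------------------------
# VCF

def _vcf_header(markers: MarkerMap, samples: list[str], with_annotations: bool) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(markers.chroms):
        header.contigs.add(str(chrom), length=int(markers.positions.max()) + 1)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.formats.add("DP", 1, "Integer", "Read depth")
    if with_annotations:
        header.info.add("GENE", 1, "String", "Gene symbol")
        header.info.add("CSQ", 1, "String", "Consequence class")
        header.info.add("CADD", 1, "Float", "CADD phred score")
        header.info.add("GMAF", 1, "Float", "gnomAD minor allele frequency")
    for s in samples:
        header.add_sample(s)
    return header


def _gt_tuple(dosage: int) -> tuple:
    if dosage == MISSING:
        return (None, None)
    return {0: (0, 0), 1: (0, 1), 2: (1, 1)}[int(dosage)]


def write_vcf(path: str, gm: GenotypeMatrix) -> None:
    """Write a genotype matrix as an uncompressed VCF (GT only)."""
    header = _vcf_header(gm.markers, gm.samples, with_annotations=False)
    with pysam.VariantFile(path, "w", header=header) as out:
        t = gm.markers.table
        for j in range(gm.n_markers):
            rec = out.new_record(
                contig=str(t.at[j, "chrom"]),
                start=int(t.at[j, "pos"]) - 1,
                stop=int(t.at[j, "pos"]),
                alleles=(str(t.at[j, "allele_a"]), str(t.at[j, "allele_b"])),
                id=str(t.at[j, "marker_id"]),
            )
            for i, s in enumerate(gm.samples):
                rec.samples[s]["GT"] = _gt_tuple(gm.genotypes[i, j])
            out.write(rec)


def read_vcf(path: str) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read an uncompressed VCF into a GenotypeMatrix plus a minimal sample table.

    Non-biallelic records are skipped with a logged count; genotypes are
    coded as ALT dosage with ``./.`` mapping to the missing sentinel.
    """
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    rows, geno = [], []
    n_skipped = 0
    with vf:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                n_skipped += 1
                continue
            rows.append(
                dict(
                    marker_id=rec.id or f"{rec.chrom}:{rec.pos}",
                    chrom=normalize_chrom(rec.chrom),
                    pos=rec.pos,
                    allele_a=rec.ref,
                    allele_b=rec.alts[0],
                )
            )
            g = np.full(len(samples), MISSING, dtype=np.int8)
            for i, s in enumerate(samples):
                alleles = rec.samples[s].get("GT", (None, None))
                if alleles is None or any(a is None for a in alleles):
                    continue
                g[i] = sum(1 for a in alleles if a != 0)
            geno.append(g)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic records in %s", n_skipped, path)
    markers = MarkerMap(pd.DataFrame(rows))
    gm = GenotypeMatrix(samples, markers, np.array(geno, dtype=np.int8).T.reshape(len(samples), -1))
    sample_table = make_sample_table(
        pd.DataFrame(
            dict(sample_id=samples, family_id=samples, sex="unknown", role="control")
        )
    )
    return gm, sample_table


def write_variant_table_vcf(path: str, table: AnnotatedVariantTable) -> None:
    """Write an annotated variant table as a VCF with GENE/CSQ/CADD/GMAF INFO."""
    v = table.variants
    mm = MarkerMap(
        pd.DataFrame(
            dict(
                marker_id=[f"v{i}" for i in range(len(v))],
                chrom=v["chrom"], pos=v["pos"], allele_a=v["ref"], allele_b=v["alt"],
            )
        ).sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    )
    header = _vcf_header(mm, table.samples, with_annotations=True)
    with pysam.VariantFile(path, "w", header=header) as out:
        for j in range(len(v)):
            rec = out.new_record(
                contig=str(v.at[j, "chrom"]),
                start=int(v.at[j, "pos"]) - 1,
                alleles=(str(v.at[j, "ref"]), str(v.at[j, "alt"])),
            )
            rec.stop = int(v.at[j, "pos"]) + len(str(v.at[j, "ref"])) - 1
            rec.info["GENE"] = str(v.at[j, "gene"])
            rec.info["CSQ"] = str(v.at[j, "consequence"])
            rec.info["CADD"] = float(v.at[j, "cadd"])
            if np.isfinite(v.at[j, "gnomad_maf"]):
                rec.info["GMAF"] = float(v.at[j, "gnomad_maf"])
            for i, s in enumerate(table.samples):
                rec.samples[s]["GT"] = _gt_tuple(table.gt[j, i])
                rec.samples[s]["GQ"] = int(table.gq[j, i])
                rec.samples[s]["DP"] = int(table.dp[j, i])
            out.write(rec)


def read_variant_table_vcf(path: str) -> AnnotatedVariantTable:
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    rows, gts, gqs, dps = [], [], [], []
    n_skipped = 0
    with vf:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                n_skipped += 1
                continue
            rows.append(
                dict(
                    chrom=normalize_chrom(rec.chrom),
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    gene=rec.info.get("GENE", ""),
                    consequence=rec.info.get("CSQ", "other"),
                    cadd=float(rec.info.get("CADD", 0.0)),
                    gnomad_maf=float(rec.info["GMAF"]) if "GMAF" in rec.info else np.nan,
                )
            )
            gt = np.full(len(samples), MISSING, dtype=np.int8)
            gq = np.zeros(len(samples))
            dp = np.zeros(len(samples), dtype=np.int32)
            for i, s in enumerate(samples):
                fmt = rec.samples[s]
                alleles = fmt.get("GT", (None, None))
                if alleles is not None and not any(a is None for a in alleles):
                    gt[i] = sum(1 for a in alleles if a != 0)
                gq[i] = fmt.get("GQ") if fmt.get("GQ") is not None else 0
                dp[i] = fmt.get("DP") if fmt.get("DP") is not None else 0
            gts.append(gt)
            gqs.append(gq)
            dps.append(dp)
    if n_skipped:
        logger.info("read_variant_table_vcf: skipped %d non-biallelic records", n_skipped)
    return AnnotatedVariantTable(
        pd.DataFrame(rows), samples,
        np.array(gts, dtype=np.int8).reshape(len(rows), len(samples)),
        np.array(gqs).reshape(len(rows), len(samples)),
        np.array(dps, dtype=np.int32).reshape(len(rows), len(samples)),
    )


# ---------------------------------------------------------------------------
# PLINK-style text genotypes

def write_plink_text(prefix: str, gm: GenotypeMatrix, samples: pd.DataFrame | None = None) -> None:
    """Write ``.ped``/``.map`` files; the .map carries allele_a/allele_b columns."""
    t = gm.markers.table
    with open(prefix + ".map", "w") as out:
        for _, r in t.iterrows():
            out.write(f"{r['chrom']}\t{r['marker_id']}\t0\t{r['pos']}\t{r['allele_a']}\t{r['allele_b']}\n")
    a = t["allele_a"].to_numpy()
    b = t["allele_b"].to_numpy()
    if samples is not None:
        samples = samples.set_index("sample_id")
    with open(prefix + ".ped", "w") as out:
        for i, sid in enumerate(gm.samples):
            if samples is not None and sid in samples.index:
                row = samples.loc[sid]
                sex = {"male": "1", "female": "2"}.get(str(row["sex"]), "0")
                meta = [str(row["family_id"]), sid, row["father_id"] or "0", row["mother_id"] or "0", sex, "0"]
            else:
                meta = [sid, sid, "0", "0", "0", "0"]
            fields = list(meta)
            for j in range(gm.n_markers):
                g = gm.genotypes[i, j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [a[j], a[j]]
                elif g == 1:
                    fields += [a[j], b[j]]
                else:
                    fields += [b[j], b[j]]
            out.write("\t".join(fields) + "\n")


def read_plink_text(prefix: str) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read ``.ped``/``.map`` text genotypes.

    If the .map lacks the allele columns, allele_b is designated as the
    minor allele observed in the .ped (ties broken alphabetically).
    """
    map_rows = []
    with open(prefix + ".map") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) not in (4, 6):
                raise ParseError(f"{prefix}.map line {ln}: expected 4 or 6 columns, got {len(parts)}")
            map_rows.append(parts)
    n_markers = len(map_rows)
    ped_rows = []
    with open(prefix + ".ped") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * n_markers:
                raise ParseError(
                    f"{prefix}.ped line {ln}: expected {6 + 2 * n_markers} fields, got {len(parts)}"
                )
            ped_rows.append(parts)
    sample_ids = [r[1] for r in ped_rows]
    alleles = np.array([r[6:] for r in ped_rows], dtype=object).reshape(len(ped_rows), n_markers, 2)

    allele_a, allele_b = [], []
    for j, mrow in enumerate(map_rows):
        if len(mrow) == 6:
            allele_a.append(mrow[4])
            allele_b.append(mrow[5])
        else:
            obs = [x for x in alleles[:, j, :].ravel() if x != "0"]
            uniq, counts = np.unique(obs, return_counts=True)
            if len(uniq) == 0:
                allele_a.append("A"); allele_b.append("B")
            elif len(uniq) == 1:
                allele_a.append(str(uniq[0])); allele_b.append("B" if uniq[0] != "B" else "A")
            else:
                order = np.argsort(counts, kind="stable")
                allele_b.append(str(uniq[order[0]]))
                allele_a.append(str(uniq[order[-1]]))
    markers = MarkerMap(
        pd.DataFrame(
            dict(
                marker_id=[r[1] for r in map_rows],
                chrom=[r[0] for r in map_rows],
                pos=[int(r[3]) for r in map_rows],
                allele_a=allele_a,
                allele_b=allele_b,
            )
        )
    )
    geno = np.full((len(sample_ids), n_markers), MISSING, dtype=np.int8)
    for j in range(n_markers):
        col = alleles[:, j, :]
        called = (col != "0").all(axis=1)
        dos = (col == allele_b[j]).sum(axis=1)
        geno[called, j] = dos[called]
        bad = called & ~np.isin(col, [allele_a[j], allele_b[j], "0"]).all(axis=1)
        if bad.any():
            raise ParseError(f"{prefix}.ped: allele not in {{{allele_a[j]},{allele_b[j]}}} at marker {j + 1}")
    gm = GenotypeMatrix(sample_ids, markers, geno)
    sex_map = {"1": "male", "2": "female"}
    sample_table = make_sample_table(
        pd.DataFrame(
            dict(
                sample_id=sample_ids,
                family_id=[r[0] for r in ped_rows],
                father_id=[r[2] if r[2] != "0" else "" for r in ped_rows],
                mother_id=[r[3] if r[3] != "0" else "" for r in ped_rows],
                sex=[sex_map.get(r[4], "unknown") for r in ped_rows],
                role="control",
            )
        )
    ) if all((r[2] == "0" or r[2] in sample_ids) and (r[3] == "0" or r[3] in sample_ids) for r in ped_rows) else pd.DataFrame()
    return gm, sample_table


def read_genotypes(path: str, format: str) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Dispatch to the VCF or PLINK-text reader.

    ``path`` is the file for VCF and the .ped/.map prefix for plink_text.
    """
    if format == "vcf":
        return read_vcf(path)
    if format == "plink_text":
        return read_plink_text(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# CNV BED(+)

_BED_COLS = ["chrom", "bed_start", "bed_end", "sample_id", "type", "source",
             "confidence", "n_probes_or_targets", "segdup_overlap_fraction"]


def read_cnv_bed(path: str) -> pd.DataFrame:
    """Read CNV calls from a BED+6 file into the internal 1-based table."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) != len(_BED_COLS):
                raise ParseError(f"{path} line {ln}: expected {len(_BED_COLS)} columns, got {len(parts)}")
            start, end = int(parts[1]), int(parts[2])
            if start >= end:
                raise ParseError(f"{path} line {ln}: BED start {start} >= end {end}")
            rows.append(
                dict(
                    sample_id=parts[3],
                    chrom=normalize_chrom(parts[0]),
                    start=start + 1,   # BED half-open 0-based -> 1-based inclusive
                    end=end,
                    type=parts[4],
                    source=parts[5],
                    confidence=float(parts[6]),
                    n_probes_or_targets=int(parts[7]),
                    segdup_overlap_fraction=float(parts[8]),
                )
            )
    return make_cnv_table(pd.DataFrame(rows, columns=[c for c in rows[0]] if rows else
                                       ["sample_id", "chrom", "start", "end", "type", "source",
                                        "confidence", "n_probes_or_targets", "segdup_overlap_fraction"]))


def write_cnv_bed(path: str, table: pd.DataFrame) -> None:
    """Write a CNV table as BED+6 (coordinates converted back to 0-based half-open)."""
    with open(path, "w") as out:
        for _, r in table.iterrows():
            out.write(
                "\t".join(
                    str(x) for x in (
                        r["chrom"], int(r["start"]) - 1, int(r["end"]), r["sample_id"],
                        r["type"], r["source"], r["confidence"],
                        int(r["n_probes_or_targets"]), r["segdup_overlap_fraction"],
                    )
                ) + "\n"
            )


# ---------------------------------------------------------------------------
# TSV: gene sets, summary stats, sample tables

def read_gene_sets(path: str) -> GeneSetCollection:
    """Two-column TSV (set name, gene symbol); duplicates collapsed."""
    df = pd.read_csv(path, sep="\t", header=None, names=["set", "gene"], dtype=str)
    n_dups = int(df.duplicated().sum())
    if n_dups:
        logger.info("read_gene_sets: collapsed %d duplicate rows in %s", n_dups, path)
    sets = {name: frozenset(grp["gene"]) for name, grp in df.groupby("set", sort=False)}
    return GeneSetCollection(sets)


def write_gene_sets(path: str, collection: GeneSetCollection) -> None:
    with open(path, "w") as out:
        for name in collection.names():
            for gene in sorted(collection[name]):
                out.write(f"{name}\t{gene}\n")


def read_summary_stats(path: str) -> pd.DataFrame:
    """Four-column TSV (marker_id, effect_allele, beta, p); invalid p rejected."""
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "effect_allele": str})
    bad = (df["p"] <= 0) | (df["p"] > 1) | df["p"].isna()
    if bad.any():
        logger.warning("read_summary_stats: rejected %d records with invalid p", int(bad.sum()))
    return make_summary_stats(df.loc[~bad].reset_index(drop=True))


def write_summary_stats(path: str, stats: pd.DataFrame) -> None:
    stats[["marker_id", "effect_allele", "beta", "p"]].to_csv(path, sep="\t", index=False)


def read_sample_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "family_id": str,
                                            "father_id": str, "mother_id": str})
    return make_sample_table(df)


def write_sample_table(path: str, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)
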