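"""End-to-end orchestration: simulate (or accept) a cohort and run every stage.

The pipeline mirrors the analysis of an isolate case-control study:
marker QC, IBS/MDS population structure with relatedness exclusions,
ROH-based inbreeding, rare homozygous deleterious load, CNV gene-set
burden, polygenic scoring with a threshold scan, covariate-adjusted group
tests, post-hoc power, and hierarchical case stratification.  The result
is a machine-readable manifest recording every threshold used.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import cnv as cnvmod
from . import gps as gpsmod
from . import popstruct, power, roh, stats, stratify, variants
from .simulate import SimConfig, SyntheticCohort, simulate_cohort


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {exc}")
        self.stage = stage


def run_pipeline(config: SimConfig | None = None, cohort: SyntheticCohort | None = None,
                 out_path: str | None = None) -> dict:
    """Run every analysis stage on a synthetic (or supplied) cohort.

    Returns a JSON-serializable manifest; when ``out_path`` is given the
    manifest is also written there.  Identical config + seed give a
    byte-identical manifest.
    """
    manifest: dict = {}
    stage = "simulate"
    try:
        if cohort is None:
            config = config or SimConfig()
            cohort = simulate_cohort(config)
        manifest["config"] = {k: (v if not isinstance(v, dict) else dict(v))
                              for k, v in asdict(cohort.config).items()}
        samples = cohort.samples
        roles = samples.set_index("sample_id")["role"]
        case_ids = samples.loc[samples["role"] == "case", "sample_id"].tolist()
        control_ids = samples.loc[samples["role"] == "control", "sample_id"].tolist()

        stage = "qc"
        qc_gm, qc_report = popstruct.qc_filter_markers(
            cohort.genotypes, popstruct.GWAS_PROFILE)
        manifest["qc"] = qc_report

        stage = "popstruct"
        cohort_ids = case_ids + control_ids
        sub = qc_gm.subset_samples(cohort_ids)
        ibs = popstruct.ibs_distance_matrix(sub)
        mds = popstruct.classical_mds(ibs, k=3)
        excl = popstruct.flag_related_or_outlier(ibs, sub.call_rate_per_sample())
        manifest["popstruct"] = dict(
            n_pairs_related=len(excl.related), n_outliers=len(excl.outliers),
            excluded=excl.excluded,
        )
        pcs = {sid: mds[i, :].tolist() for i, sid in enumerate(sub.samples)}

        stage = "roh"
        froh = roh.froh_per_sample(qc_gm.subset_samples(cohort_ids))
        froh_by_id = froh.set_index("sample_id")["f_roh"]
        case_mask = np.array([roles[s] == "case" for s in cohort_ids])
        cov = np.array([pcs[s][:3] for s in cohort_ids])
        f_test = stats.adjusted_mannwhitney(
            froh_by_id[cohort_ids].to_numpy(), case_mask, covariates=cov,
            alternative="greater", covariate_names=["PC1", "PC2", "PC3"])
        manifest["inbreeding"] = dict(
            median_f_case=float(froh_by_id[case_ids].median()),
            median_f_control=float(froh_by_id[control_ids].median()),
            u=f_test.u, p_one_sided=f_test.p,
        )

        stage = "variant_load"
        filt = variants.RarityFilter(max_gnomad_maf=0.01)
        ctrl_mask = np.array([roles[s] == "control" for s in cohort.variants.samples])
        vtab, vreport = variants.apply_rarity_filter(cohort.variants, filt, ctrl_mask)
        manifest["variant_filter"] = vreport
        profiles = {s: variants.homozygous_load(vtab, s, gene_sets=cohort.gene_sets)
                    for s in cohort_ids}
        loads = np.array([profiles[s].n_hom_deleterious for s in cohort_ids])
        load_test = stats.adjusted_mannwhitney(
            loads, case_mask,
            covariates=froh_by_id[cohort_ids].to_numpy()[:, None],
            alternative="greater", covariate_names=["f_roh"])
        hit_summary, hit_fisher = variants.gene_set_hit_test(
            [profiles[s] for s in case_ids], [profiles[s] for s in control_ids],
            cohort.gene_sets)
        manifest["load"] = dict(
            mean_load_case=float(loads[case_mask].mean()),
            mean_load_control=float(loads[~case_mask].mean()),
            u=load_test.u, p_one_sided=load_test.p,
            geneset_carrier_p=hit_fisher.p,
        )

        stage = "cnv"
        params = cnvmod.CNVFilterParams()
        kept, cnv_report = cnvmod.filter_cnvs(cohort.cnvs, params)
        freqs = cnvmod.cnv_frequency(kept, cohort_ids, params.target_overlap_min)
        rare = kept.loc[freqs <= params.rare_max_freq].reset_index(drop=True)
        burden_rows = {}
        for cnv_type in ("deletion", "duplication"):
            summary, fisher = cnvmod.cnv_geneset_burden(
                rare, cohort.genes, cohort.gene_sets, case_ids, control_ids,
                cnv_type=cnv_type)
            burden_rows[cnv_type] = dict(
                carriers_case=int(summary.loc[0, "carriers"]),
                carriers_control=int(summary.loc[1, "carriers"]),
                p_one_sided=fisher.p,
                p_bonferroni=summary.attrs["p_bonferroni"],
                odds_ratio=fisher.odds_ratio,
            )
        manifest["cnv"] = dict(filter=cnv_report, burden=burden_rows)

        stage = "gps"
        pheno = case_mask.astype(float)
        scan = gpsmod.threshold_scan(qc_gm.subset_samples(cohort_ids),
                                     cohort.summary_stats, pheno)
        gps_cov = np.column_stack([cov, froh_by_id[cohort_ids].to_numpy()])
        gps_test = stats.adjusted_mannwhitney(
            scan.scores.to_numpy(), case_mask, covariates=gps_cov,
            alternative="greater", covariate_names=["PC1", "PC2", "PC3", "f_roh"])
        manifest["gps"] = dict(best_threshold=scan.best_threshold,
                               r2_at_best=scan.r2_at_best,
                               u=gps_test.u, p_one_sided=gps_test.p)

        stage = "power"
        n1, n2 = len(case_ids), len(control_ids)
        d_obs = _cohens_d(froh_by_id[case_ids].to_numpy(), froh_by_id[control_ids].to_numpy())
        manifest["power"] = dict(
            d_observed_inbreeding=d_obs,
            achieved_power_inbreeding=power.wmw_power(power.PowerSpec(n1, n2, abs(d_obs))),
            required_d_power80=power.wmw_required_d(n1, n2),
        )

        stage = "stratify"
        cnv_hits = cnvmod.cnv_gene_hits(rare, cohort.genes)
        feats = stratify.build_feature_table(
            [profiles[s] for s in case_ids], cnv_hits, scan.scores, cohort.gene_sets,
            set_name=list(cohort.gene_sets.names())[0], case_samples=case_ids)
        k = min(3, len(feats))
        clusters = stratify.hierarchical_cluster(feats, k=k)
        summary = stratify.cluster_summary(
            clusters.labels, samples[["sample_id", "has_id", "sex"]])
        manifest["stratification"] = dict(
            k=k, cluster_sizes=summary.set_index("cluster")["n"].to_dict(),
            pct_id={int(r["cluster"]): float(r["pct_id"]) for _, r in summary.iterrows()},
        )
    except Exception as exc:   # noqa: BLE001 - stage-named abort per contract
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc

    if out_path is not None:
        with open(out_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    sp = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2))
    if sp == 0:
        return 0.0
    return float((x.mean() - y.mean()) / sp)
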