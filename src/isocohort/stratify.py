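"""Genetic stratification of cases by hierarchical clustering.

Cases are clustered on two genetic features only — the number of
candidate-set genes hit by a rare deleterious SNV or CNV, and the
polygenic score — with clinical flags carried along as annotations.
Features are z-scored, distances are Euclidean, linkage is Ward, and the
tree is cut to k clusters whose labels are ordered by descending mean
polygenic score so the labelling is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger("isocohort")


def build_feature_table(
    load_profiles: list,
    cnv_hits: pd.Series,
    gps_scores: pd.Series,
    gene_sets,
    set_name: str = "SFARI",
    case_samples: list[str] | None = None,
) -> pd.DataFrame:
    """Per-case features: distinct candidate-set genes hit (SNV or CNV) + GPS.

    A gene counts once no matter how many variants or calls hit it.  Cases
    without a polygenic score are excluded with a logged count.
    """
    target = gene_sets[set_name]
    snv_genes = {p.sample_id: set(p.genes_hit) for p in load_profiles}
    rows = []
    samples = case_samples if case_samples is not None else sorted(snv_genes)
    n_dropped = 0
    for sid in samples:
        if sid not in gps_scores.index or pd.isna(gps_scores[sid]):
            n_dropped += 1
            continue
        genes = (snv_genes.get(sid, set()) | set(cnv_hits.get(sid, set()))) & target
        rows.append(dict(sample_id=sid, n_set_genes_hit=len(genes),
                         gps=float(gps_scores[sid])))
    if n_dropped:
        logger.info("build_feature_table: dropped %d cases without a GPS", n_dropped)
    return pd.DataFrame(rows)


@dataclass
class ClusterResult:
    labels: pd.Series           # sample_id -> 1..k, ordered by descending mean GPS
    linkage_table: np.ndarray
    features_scaled: pd.DataFrame


def hierarchical_cluster(features: pd.DataFrame, k: int = 3,
                         feature_cols: tuple[str, ...] = ("n_set_genes_hit", "gps")
                         ) -> ClusterResult:
    """Ward clustering of z-scored features, tree cut to ``k`` clusters."""
    if len(features) < k:
        raise ValueError(f"need at least k={k} samples, got {len(features)}")
    x = features[list(feature_cols)].to_numpy(dtype=float)
    scaled = np.empty_like(x)
    for c in range(x.shape[1]):
        sd = x[:, c].std(ddof=0)
        if sd == 0:
            logger.warning("hierarchical_cluster: constant feature %r left unscaled",
                           feature_cols[c])
            scaled[:, c] = 0.0
        else:
            scaled[:, c] = (x[:, c] - x[:, c].mean()) / sd
    if k == 1:
        raw = np.ones(len(features), dtype=int)
        lk = linkage(scaled, method="ward") if len(features) > 1 else np.empty((0, 4))
    else:
        lk = linkage(scaled, method="ward")
        raw = fcluster(lk, t=k, criterion="maxclust")
    # relabel clusters by descending mean GPS for determinism
    df = pd.DataFrame(dict(raw=raw, gps=features["gps"].to_numpy()))
    order = df.groupby("raw")["gps"].mean().sort_values(ascending=False).index
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([remap[r] for r in raw],
                       index=features["sample_id"].to_numpy(), name="cluster")
    scaled_df = pd.DataFrame(scaled, columns=list(feature_cols),
                             index=features["sample_id"].to_numpy())
    return ClusterResult(labels, lk, scaled_df)


def cluster_summary(labels: pd.Series, clinical: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster composition: n, % with ID, sex ratio and flag counts.

    ``clinical`` must have sample_id plus has_id / sex; extra boolean flag
    columns (e.g. epilepsy, preterm) are counted as well.
    """
    c = clinical.set_index("sample_id").loc[labels.index]
    c = c.assign(cluster=labels.to_numpy())
    extra_flags = [col for col in c.columns
                   if col not in ("cluster", "has_id", "sex") and c[col].dtype == bool]
    rows = []
    for cl, grp in c.groupby("cluster"):
        row = dict(cluster=cl, n=len(grp),
                   pct_id=100.0 * grp["has_id"].mean(),
                   n_male=int((grp["sex"] == "male").sum()),
                   n_female=int((grp["sex"] == "female").sum()))
        for flag in extra_flags:
            row[f"n_{flag}"] = int(grp[flag].sum())
        rows.append(row)
    return pd.DataFrame(rows).sort_values("cluster").reset_index(drop=True)
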