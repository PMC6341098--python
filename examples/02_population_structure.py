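"""Marker QC, pairwise IBS distance, classical MDS and sample exclusions.

The pairwise distance is 1 - (0.5*IBS1 + IBS2)/N over markers called in
both samples; near-duplicate pairs (similarity > 0.9) and MDS outliers
are flagged for exclusion, as one would before any association analysis.
"""

import numpy as np

from isocohort import (GWAS_PROFILE, SimConfig, classical_mds,
                       flag_related_or_outlier, ibs_distance_matrix,
                       qc_filter_markers, simulate_cohort)

cohort = simulate_cohort(SimConfig(seed=7, n_case_families=10, n_control_samples=25,
                                   n_chromosomes=2, n_markers_per_chromosome=300))
gm, report = qc_filter_markers(cohort.genotypes, GWAS_PROFILE)
print(f"marker QC: {report}")

roles = cohort.samples.set_index("sample_id")["role"]
cohort_ids = [s for s in gm.samples if roles[s] in ("case", "control")]
sub = gm.subset_samples(cohort_ids)

ibs = ibs_distance_matrix(sub)
off_diag = ibs.distances[np.triu_indices(len(cohort_ids), k=1)]
print(f"median pairwise IBS distance: {np.median(off_diag):.4f} "
      f"(0 = identical genotypes, 1 = opposite homozygotes everywhere)")

coords = classical_mds(ibs, k=2)
print(f"MDS component 1 spans [{coords[:, 0].min():.3f}, {coords[:, 0].max():.3f}]")

excl = flag_related_or_outlier(ibs, sub.call_rate_per_sample())
print(f"flagged for exclusion: related={excl.related} outliers={excl.outliers}")
# In a homogeneous simulated cohort without duplicates both lists are
# typically empty; a planted duplicate would flag its lower-call-rate copy.
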