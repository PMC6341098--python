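import numpy as np
import pandas as pd
import pytest

from isocohort.datamodel import GenotypeMatrix, MarkerMap
from isocohort.simulate import SimConfig, simulate_cohort


def make_marker_map(n_markers: int, chrom: str = "1", spacing: int = 1000,
                    start: int = 1) -> MarkerMap:
    return MarkerMap(pd.DataFrame(dict(
        marker_id=[f"m{chrom}_{j}" for j in range(n_markers)],
        chrom=chrom,
        pos=[start + j * spacing for j in range(n_markers)],
        allele_a="A",
        allele_b="B",
    )))


def make_gm(genotypes, chrom="1", spacing=1000) -> GenotypeMatrix:
    g = np.asarray(genotypes, dtype=np.int8)
    mm = make_marker_map(g.shape[1], chrom=chrom, spacing=spacing)
    return GenotypeMatrix([f"S{i}" for i in range(g.shape[0])], mm, g)


@pytest.fixture(scope="session")
def small_cohort():
    """One shared small synthetic cohort for cross-module tests."""
    cfg = SimConfig(
        seed=7, n_case_families=10, n_control_samples=25,
        n_chromosomes=2, n_markers_per_chromosome=300,
        n_lgd=40, n_mis30=40, n_other=80, n_genes=100,
        geneset_sizes={"SFARI": 20, "PLI09": 25, "BRAIN": 30},
        n_causal_markers=12,
    )
    return simulate_cohort(cfg)
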