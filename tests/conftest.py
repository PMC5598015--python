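import numpy as np
import pandas as pd
import pytest

from cardioqtl.synthetic import CohortConfig, PlantedEffects, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def null_cohort():
    """Small cohort with no planted effects."""
    cfg = CohortConfig(
        n_cases=30, n_controls=30, n_genes=20, n_snps=40, n_ase_sites=8, seed=11
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort carrying one effect of each class."""
    effects = PlantedEffects(
        eqtl=[("G0001", "rs00001", 0.5)],
        group_eqtl=[("G0002", "rs00002", 0.8, "case")],
        de=[("G0003", 1.0)],
        dpsi=[("G0004:E001", 0.3)],
        sqtl=[("G0005", "G0005:E001", "rs00005", 0.2)],
        ase=[("site_001", 0.75)],
    )
    cfg = CohortConfig(
        n_cases=50,
        n_controls=50,
        n_genes=20,
        n_snps=40,
        n_exons_per_gene=(3, 5),
        n_ase_sites=8,
        ase_coverage=150.0,
        effects=effects,
        seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def toy_counts():
    return pd.DataFrame(
        {
            "s1": [10, 20, 30, 40],
            "s2": [20, 40, 60, 80],
            "s3": [5, 10, 15, 20],
        },
        index=["g1", "g2", "g3", "g4"],
        dtype=float,
    )
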