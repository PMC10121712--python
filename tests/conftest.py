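import numpy as np
import pytest

from snstates import CellTypeSpec, CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """8 subjects x 150 nuclei, one cell type with 3 states, no planted effects."""
    cfg = CohortConfig(
        seed=11,
        n_subjects=8,
        nuclei_per_subject=150,
        cell_types=[CellTypeSpec("microglia", 3)],
        n_genes=200,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def state_cohort():
    """Cohort with strong state-specific expression for clustering/transfer."""
    de = {}
    for st in range(3):
        for g in range(100 + st * 20, 100 + st * 20 + 20):
            de[(f"microglia.{st}", g)] = 1.5
    cfg = CohortConfig(
        seed=21,
        n_subjects=8,
        nuclei_per_subject=150,
        cell_types=[CellTypeSpec("microglia", 3)],
        n_genes=200,
        de_effects=de,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def qc_cohort():
    """Cohort with planted ambient barcodes, doublets and high-mito nuclei."""
    cfg = CohortConfig(
        seed=31,
        n_subjects=4,
        nuclei_per_subject=150,
        cell_types=[CellTypeSpec("microglia", 2)],
        n_genes=150,
        mito_high_fraction=0.1,
        doublet_rate=0.05,
        ambient_barcodes=3000,
    )
    return generate_cohort(cfg)
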