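import pandas as pd
import pytest

import parainflam as pf


@pytest.fixture(scope="session")
def small_config() -> pf.SimConfig:
    """A compact cohort: 2 tissues, 60 tumors + 40 normals each."""
    return pf.SimConfig(
        seed=11,
        n_genes=400,
        n_tissues=2,
        n_tumors_per_tissue=60,
        n_normals_per_tissue=40,
        n_inflammatory_genes=80,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    expr, ann, truth = pf.simulate_tumor_cohort(small_config)
    return expr, ann, truth


@pytest.fixture(scope="session")
def reference_normals(small_config):
    return pf.simulate_reference_normals(small_config)


@pytest.fixture(scope="session")
def cell_panel():
    cfg = pf.SimConfig(seed=9, n_genes=400, n_cell_lines=600,
                       n_inflammatory_genes=80)
    return pf.simulate_cell_line_panel(cfg)


@pytest.fixture(scope="session")
def count_experiment():
    cfg = pf.SimConfig(
        seed=5, n_genes=600, n_replicates=3, n_de_genes=60,
        de_log2fc=2.5, shared_de_fraction=0.6, n_inflammatory_genes=120,
    )
    return pf.simulate_counts(cfg)
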