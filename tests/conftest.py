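import numpy as np
import pandas as pd
import pytest

from dcmlnc import SimulationConfig, run_preprocessing, simulate_study


SMALL = dict(
    n_chromosomes=3,
    chrom_length=2_000_000,
    n_coding=80,
    n_lnc_per_class=12,
    n_hubs=2,
    module_size=10,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, **SMALL)


@pytest.fixture(scope="session")
def small_study(small_config):
    """(study, truth, annotation) for a compact 60-lncRNA / 80-mRNA design."""
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_norm(small_study):
    study, _, _ = small_study
    norm, filtered = run_preprocessing(study)
    return norm, filtered


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def tiny_norm():
    """Hand-built normalized matrix: 4 probes x 8 samples, 2 groups."""
    from dcmlnc import NormalizedMatrix

    samples = [f"control_6wk_r{i}" for i in range(1, 5)] + [f"dbdb_6wk_r{i}" for i in range(1, 5)]
    meta = pd.DataFrame(
        {
            "genotype": ["control"] * 4 + ["dbdb"] * 4,
            "age": [6] * 8,
            "replicate": [1, 2, 3, 4] * 2,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    values = pd.DataFrame(
        [
            [5.0, 5.1, 4.9, 5.0, 7.0, 7.1, 6.9, 7.0],  # clear up
            [8.0, 8.1, 7.9, 8.0, 8.0, 8.1, 7.9, 8.0],  # null
            [6.0, 6.1, 5.9, 6.0, 3.0, 3.1, 2.9, 3.0],  # clear down
            [4.0, 4.0, 4.0, 4.0, 4.0, 4.0, 4.0, 4.0],  # constant
        ],
        index=pd.Index(["P1", "P2", "P3", "P4"], name="probe_id"),
        columns=samples,
    )
    return NormalizedMatrix(values), meta
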