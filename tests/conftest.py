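import numpy as np
import pytest

from cultnet.synthetic import generate_cultural_dataset


THREE_REGIONS = {
    "n_per_region": {"Poly": 20, "Micro": 20, "Mela": 20},
    "region_params": {"Poly": [8, 1, 1], "Micro": [1, 8, 1], "Mela": [1, 1, 8]},
}


@pytest.fixture(scope="session")
def small_dataset():
    """60 societies x 24 ordinal traits from 3 well-separated archetypes,
    15% missing — the workhorse fixture for the imputation/archetype path."""
    tm, truth = generate_cultural_dataset(
        THREE_REGIONS["n_per_region"],
        p=24,
        k=3,
        region_params=THREE_REGIONS["region_params"],
        ordinal_levels=6,
        noise_sd=0.02,
        missing_rate=0.15,
        seed=11,
    )
    return tm, truth


@pytest.fixture(scope="session")
def clean_low_noise_X(small_dataset):
    """Completed centred matrix for archetype tests (fit once per session)."""
    from cultnet.vbpca import fit_vbpca, impute

    tm, truth = small_dataset
    model = fit_vbpca(tm, seed=5)
    return impute(model), tm, truth, model
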