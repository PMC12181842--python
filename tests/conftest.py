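import numpy as np
import pandas as pd
import pytest

from socpd.phenotyping import HCReference
from socpd.synth import CohortConfig, generate_cohort, generate_reference_controls


@pytest.fixture(scope="session")
def small_cfg() -> CohortConfig:
    return CohortConfig(n_hc=80, n_prodromal=80, n_clinical=80, seed=3)


@pytest.fixture(scope="session")
def hc_ref(small_cfg) -> HCReference:
    ref, _ = generate_reference_controls(small_cfg)
    return ref


@pytest.fixture(scope="session")
def visits(small_cfg, hc_ref) -> pd.DataFrame:
    return generate_cohort(small_cfg, hc_ref)


@pytest.fixture(scope="session")
def baseline_phenotypes(visits) -> pd.DataFrame:
    base = visits[visits["time_years"] == 0]
    return base[["subject_id", "true_phenotype"]].drop_duplicates("subject_id")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_connected_affinity(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric nonnegative affinity guaranteed connected via a chain."""
    W = rng.random((n, n))
    W = (W + W.T) / 2.0
    W[W < 0.3] = 0.0  # sparsify
    for i in range(n - 1):  # chain keeps it connected
        W[i, i + 1] = W[i + 1, i] = max(W[i, i + 1], 0.5)
    np.fill_diagonal(W, 0.0)
    return W
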