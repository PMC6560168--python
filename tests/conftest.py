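import numpy as np
import pytest

from cytomatch import build_panel_template, sample_cohort
from cytomatch.datasets import DonorEffect


@pytest.fixture(scope="session")
def mini_template():
    return build_panel_template("mini")


@pytest.fixture(scope="session")
def full_template():
    return build_panel_template("full")


@pytest.fixture(scope="session")
def mini_cohort(mini_template):
    """Small discrete-lineage cohort: 2 donors x 1,500 cells."""
    return sample_cohort(
        mini_template, n_donors=2, cells_per_donor=1500,
        effect=DonorEffect(n_donors=2), seed=42,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
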