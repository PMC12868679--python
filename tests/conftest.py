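import warnings

import numpy as np
import pytest

from metatme.core import default_panel
from metatme.synthetic import SyntheticConfig, generate_cohort

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", message=".*convergence.*")


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_cohort(panel):
    """A 12-patient cohort with the default study conditions, shared read-only."""
    cfg = SyntheticConfig(
        n_patients=12, cells_per_core=(400, 500), seed=11, censor_rate=0.02
    )
    cells, clinical = generate_cohort(cfg, panel=panel)
    return cells, clinical


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
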