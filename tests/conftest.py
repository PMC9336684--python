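import numpy as np
import pytest

from pegtk import config
from pegtk.pk_core import DoseRegimen, HumanPKParams, MonkeyPKParams


@pytest.fixture(scope="session")
def monkey_truth() -> MonkeyPKParams:
    return config.MONKEY_TRUTH


@pytest.fixture(scope="session")
def human_truth() -> HumanPKParams:
    return config.HUMAN_TRUTH


@pytest.fixture(scope="session")
def pd_truth():
    return config.PD_TRUTH


@pytest.fixture
def weekly_regimen():
    return DoseRegimen(dose=1.0, tau=168.0, nDoses=1)


@pytest.fixture
def week_grid():
    return np.linspace(0.0, 168.0, 337)
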