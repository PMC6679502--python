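import pytest

from lodlamp.control import ControllerConfig
from lodlamp.thermal import calibrate_plant
from lodlamp.tocs import TOCSModel


@pytest.fixture
def plant():
    """Default-calibrated plant: ambient 25 C, 70 C at duty 0.5, tau 60 s."""
    return calibrate_plant(25.0, 70.0, 60.0)


@pytest.fixture
def tocs_model():
    return TOCSModel()


@pytest.fixture
def controller_cfg():
    return ControllerConfig()
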