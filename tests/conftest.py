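import importlib.util
import sys
from pathlib import Path

import pytest

from ecmech import ProbeCalibration, RampConfig

REPO_ROOT = Path(__file__).resolve().parent.parent


@pytest.fixture(scope="session")
def acceptance_mod():
    """The acceptance script, imported as a module so its computations can be
    exercised directly by the test suite."""
    path = REPO_ROOT / "scripts" / "acceptance.py"
    spec = importlib.util.spec_from_file_location("ecmech_acceptance", path)
    mod = importlib.util.module_from_spec(spec)
    sys.modules["ecmech_acceptance"] = mod
    spec.loader.exec_module(mod)
    return mod


@pytest.fixture
def calib():
    """Default probe: 5 N/m lever, 10 µm bead, 50 nm/V sensitivity."""
    return ProbeCalibration(spring_constant=5.0, tip_radius=1.0e4, sensitivity=50.0)


@pytest.fixture
def quiet_ramp():
    """Noise-free instrument ramp."""
    return RampConfig(noise_sd_volts=0.0)


@pytest.fixture
def noisy_ramp():
    """Default 2 mV instrument ramp."""
    return RampConfig()
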