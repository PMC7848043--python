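import numpy as np
import pytest

from circlegas import (
    CircuitConfig,
    FreshGasSettings,
    GasComposition,
    MonitorModel,
    PatientModel,
    canonical_protocol,
    run_protocol,
)


@pytest.fixture
def default_config():
    return CircuitConfig()


@pytest.fixture
def no_uptake_patient():
    return PatientModel(vo2=0.0, vco2=0.0)


@pytest.fixture
def default_patient():
    return PatientModel()


@pytest.fixture
def quiet_monitor():
    """Monitor with quantization but no reading noise."""
    return MonitorModel(noise_sd=0.0, seed=0)


@pytest.fixture
def maintenance_fg_air():
    """O2/air maintenance mixture: 68 % O2, 5 vol% sevoflurane."""
    return FreshGasSettings(fgf=1.0, delivered=GasComposition.from_delivery(68.0, 5.0, "n2"))


@pytest.fixture(scope="session")
def air_trace_fgf2():
    """Deterministic O2/air protocol trace at FGF 2 L/min (session-cached)."""
    return run_protocol(canonical_protocol("oxygen_air", 2.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
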