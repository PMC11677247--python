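import warnings

import numpy as np
import pytest

from osseowave.geometry import ModelSpec, build_model
from osseowave.materials import Fluid, default_materials

warnings.filterwarnings(
    "ignore", message="applicator thinner than one element diameter"
)


@pytest.fixture(scope="session")
def registry():
    return default_materials()


@pytest.fixture(scope="session")
def fluid():
    return Fluid()


@pytest.fixture(scope="session")
def benchmark_model():
    """The default scaled benchmark model (phase 1, d = 500 um)."""
    return build_model(ModelSpec())


# -- expensive shared computations (built once per session) -----------------

@pytest.fixture(scope="session")
def modulus_results():
    from osseowave.verify import modulus_recovery

    return {name: modulus_recovery(name) for name in ("Cortical", "Cancellous")}


@pytest.fixture(scope="session")
def wave_result():
    from osseowave.verify import wave_speed

    return wave_speed()


@pytest.fixture(scope="session")
def undrained_result():
    from osseowave.verify import undrained_response

    return undrained_response()


@pytest.fixture(scope="session")
def terzaghi_result():
    from osseowave.verify import terzaghi_benchmark

    return terzaghi_benchmark()


@pytest.fixture(scope="session")
def oscillator_result():
    from osseowave.verify import two_body_oscillator

    return two_body_oscillator()


@pytest.fixture(scope="session")
def energy_drift_value():
    from osseowave.verify import energy_drift

    return energy_drift()


@pytest.fixture(scope="session")
def convergence_table():
    """Three-discretization physiological benchmark (several CPU-minutes)."""
    from osseowave.pipeline import convergence_study

    return convergence_study(ModelSpec())


@pytest.fixture(scope="session")
def eswt_low_intensity():
    """Phase-1 pulse train at EFD 0.02 mJ/mm^2 on the scaled model."""
    from osseowave.pipeline import run_eswt

    return run_eswt(ModelSpec(), efd=0.02)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
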