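import numpy as np
import pytest

from inkflow import InkParams, NozzleSpec, reference_ink


@pytest.fixture(scope="session")
def pluronic_245() -> InkParams:
    """24.5 wt% Pluronic F-127 rheological constants."""
    return reference_ink("24.5")


@pytest.fixture(scope="session")
def nozzle_21g() -> NozzleSpec:
    return NozzleSpec.from_gauge("21G")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20160906)


@pytest.fixture()
def power_law_curve_arrays():
    """Noiseless power-law flow curve with the 24.5 wt% constants."""
    gamma = np.array([1.0, 10.0, 100.0, 1000.0])
    eta = 1.04 * gamma ** (0.0511 - 1.0)
    return gamma, eta
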