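import numpy as np
import pytest
from hypothesis import settings

from photofrag.toy_pes import ToyPES, toy_fixture

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_2tu():
    """2-thiouracil-like toy spec and its equilibrium state."""
    return toy_fixture("2TU-like", seed=0)


@pytest.fixture(scope="session")
def fixture_4tu():
    return toy_fixture("4TU-like", seed=0)


@pytest.fixture(scope="session")
def surfaces_2tu(fixture_2tu):
    spec, _ = fixture_2tu
    return ToyPES(spec, "neutral"), ToyPES(spec, "cation")


class ConstantOffsetPES:
    """Zero-force surface shifted by a constant — handy integrator stub."""

    def __init__(self, offset=0.0, charge_state="neutral"):
        self.offset = offset
        self.charge_state = charge_state

    def evaluate(self, positions):
        return self.offset, np.zeros_like(np.asarray(positions, dtype=float))


class Harmonic1DPES:
    """Single particle in a 1D harmonic well along x: V = ½ k x²."""

    charge_state = "neutral"

    def __init__(self, k):
        self.k = k

    def evaluate(self, positions):
        x = np.asarray(positions, dtype=float).reshape(-1, 3)
        grad = np.zeros_like(x)
        grad[:, 0] = self.k * x[:, 0]
        return 0.5 * self.k * float(np.sum(x[:, 0] ** 2)), grad


@pytest.fixture
def constant_pes():
    return ConstantOffsetPES


@pytest.fixture
def harmonic_pes():
    return Harmonic1DPES
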