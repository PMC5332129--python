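import numpy as np
import pytest

from exgmerge.symmetry import UnitCell


@pytest.fixture
def xfel_cell() -> UnitCell:
    return UnitCell(57.9, 84.8, 384.3)


def draw_exgauss(rng: np.random.Generator, mu: float, sigma: float, tau: float, n: int):
    """Reference sampler: Normal + independent Exponential by definition."""
    return rng.normal(mu, sigma, n) + rng.exponential(tau, n)
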