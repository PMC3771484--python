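import numpy as np
import pytest

from liverzones import (
    DensityPair,
    DimensionalParams,
    DimensionlessParams,
    GridFunction,
    uniform_grid,
)


@pytest.fixture
def example_dimensional() -> DimensionalParams:
    """A small asymmetric parameter set with hand-checkable derived constants
    (c1=0.8, c2=1.4, A=0.2, B=1.5, D=2/3)."""
    return DimensionalParams(
        K1=1.0, K2=2.0, sigma=1.0, mu1=0.2, mu2=0.6,
        nu1=1.0, nu2=0.5, k1=1.0, k2=1.0, f=1.0, c0=1.0, L=3.0,
    )


@pytest.fixture
def zone_params() -> DimensionlessParams:
    """The canonical zone-forming parameter set (x* = ln(0.8/0.3))."""
    return DimensionlessParams(theta=1.0, gamma=1.0, lam=0.5, eta=0.2, Lambda=3.0)


@pytest.fixture
def stationary_pair(zone_params) -> DensityPair:
    """The upstream-only equilibrium (v1, v2) = (e^-x, 0) on [0, Lambda]."""
    x = uniform_grid(0.0, zone_params.Lambda, 401)
    return DensityPair(GridFunction(x, np.exp(-x)), GridFunction(x, np.zeros_like(x)))
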