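import numpy as np
import pytest

from oneopes.toy_systems import DoubleWellSystem, FunnelGeometry, ToyBindingSystem


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def funnel():
    return FunnelGeometry(
        cylinder_radius=0.2,
        cone_half_angle=0.7,
        cone_to_cylinder_z=0.4,
        wall_spring_constant=5000.0,
    )


@pytest.fixture
def binding_system():
    return ToyBindingSystem()


@pytest.fixture
def double_well_system():
    return DoubleWellSystem(barrier_height=20.0, minima_sep=2.0)


def finite_difference_gradient(fn, x, h=1e-6):
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    for i in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (fn(xp) - fn(xm)) / (2 * h)
    return g
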