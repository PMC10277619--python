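import numpy as np
import pytest

from biodesulf.datasets import load_desulfurization_design
from biodesulf.growth import FITTED_PARAMS


@pytest.fixture(scope="session")
def study_design():
    return load_desulfurization_design()


@pytest.fixture(scope="session")
def fitted_growth_params():
    return FITTED_PARAMS


def rk4_integrate(rhs, y0, t_grid):
    """Fixed-step classical Runge-Kutta integrator, used as an independent
    oracle against the adaptive solvers in the package."""
    y = float(y0)
    out = [y]
    for t0, t1 in zip(t_grid[:-1], t_grid[1:]):
        h = t1 - t0
        k1 = rhs(t0, y)
        k2 = rhs(t0 + h / 2, y + h * k1 / 2)
        k3 = rhs(t0 + h / 2, y + h * k2 / 2)
        k4 = rhs(t0 + h, y + h * k3)
        y = y + h * (k1 + 2 * k2 + 2 * k3 + k4) / 6
        out.append(y)
    return np.asarray(out)
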