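import numpy as np
import pytest

from page4.calibrate import default_params
from page4.circuit import CircuitState
from page4.cohort import limit_cycle
from page4.synthetic_ensembles import default_presets, generate_ensemble


@pytest.fixture(scope="session")
def params():
    """The calibrated default circuit parameter set."""
    return default_params()


@pytest.fixture(scope="session")
def cycle(params):
    """The no-treatment limit cycle of the default parameters."""
    return limit_cycle(params)


@pytest.fixture(scope="session")
def on_cycle_ic(cycle):
    """An initial condition lying on the limit cycle (at its H peak)."""
    return CircuitState.from_array(cycle.states[0])


# -- synthetic ensembles (moderate sizes; session-cached) -----------------

_N_CONFORMERS = 120


@pytest.fixture(scope="session")
def wt_ensemble():
    return generate_ensemble(default_presets()["WT"], _N_CONFORMERS, seed=101)


@pytest.fixture(scope="session")
def hipk1_ensemble():
    return generate_ensemble(default_presets()["HIPK1"], _N_CONFORMERS, seed=102)


@pytest.fixture(scope="session")
def clk2_ensemble():
    return generate_ensemble(default_presets()["CLK2"], _N_CONFORMERS, seed=103)


def rk4_integrate(rhs, y0, t_grid):
    """Classical fixed-step RK4 on a uniform grid; independent oracle."""
    y = np.asarray(y0, dtype=float)
    out = np.empty((len(t_grid), y.size))
    out[0] = y
    for k in range(len(t_grid) - 1):
        t, h = t_grid[k], t_grid[k + 1] - t_grid[k]
        k1 = rhs(t, y)
        k2 = rhs(t + h / 2, y + h / 2 * k1)
        k3 = rhs(t + h / 2, y + h / 2 * k2)
        k4 = rhs(t + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[k + 1] = y
    return out
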