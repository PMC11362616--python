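import numpy as np
import pytest

from pa2p.kinetics import RateParams


def rk4_three_state(k_act: float, k_bl: float, t_end: float, dt: float = 1e-3):
    """Independent RK4 integration of the three-state system.

    dN_i/dt = -k_act N_i ; dN_f/dt = k_act N_i - k_bl N_f.
    Returns N_f(t_end).  Kept deliberately separate from the package's
    closed-form implementation so the two can cross-check each other.
    """

    def deriv(state):
        ni, nf = state
        return np.array([-k_act * ni, k_act * ni - k_bl * nf])

    n_steps = max(int(np.ceil(t_end / dt)), 1)
    h = t_end / n_steps
    state = np.array([1.0, 0.0])
    for _ in range(n_steps):
        k1 = deriv(state)
        k2 = deriv(state + h / 2 * k1)
        k3 = deriv(state + h / 2 * k2)
        k4 = deriv(state + h * k3)
        state = state + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return state[1]


@pytest.fixture
def rk4_oracle():
    return rk4_three_state


@pytest.fixture
def rates_default():
    return RateParams(k_act=0.5, k_bl=0.1)
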