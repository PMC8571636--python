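import numpy as np
import pytest

from stresscomm.models import CommunityState, LVParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def worked_effect_matrix():
    """The 2x2 effect matrix of the worked intensity example."""
    return np.array([[0.8, 0.5], [0.4, 0.7]])


@pytest.fixture
def symmetric_lv_pair():
    """mu = (1,1), alpha12 = alpha21 = 0.5, alpha_ii = 1; N* = (2/3, 2/3)."""
    return LVParams(mu=[1.0, 1.0], alpha=[[1.0, 0.5], [0.5, 1.0]])


def integrate_lv(params: LVParams, N0, t_end=2000.0):
    """Time-integration oracle: long LV trajectory from N0."""
    from scipy.integrate import solve_ivp

    def dyn(_, N):
        N = np.clip(N, 0.0, None)
        return N * (params.mu - params.alpha @ N)

    sol = solve_ivp(dyn, (0.0, t_end), np.asarray(N0, float),
                    method="LSODA", rtol=1e-10, atol=1e-12)
    return np.clip(sol.y[:, -1], 0.0, None)


@pytest.fixture
def lv_time_integrator():
    return integrate_lv
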