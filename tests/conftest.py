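import numpy as np
import pytest

from rtktraffic.model_core import CompartmentState, RateParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_rates(rng, n=1, psyn_range=(-2, 3), rate_range=(-5, -1)):
    """Physiological-scale random parameter sets (log-uniform)."""
    out = []
    for _ in range(n):
        psyn = float(10 ** rng.uniform(*psyn_range))
        kd, ke, kr, ks = (float(10 ** rng.uniform(*rate_range))
                          for _ in range(4))
        out.append(RateParams(P_syn=psyn, k_deg=kd, k_end=ke,
                              k_rec=kr, k_shed=ks))
    return out if n > 1 else out[0]


def random_state(rng, scale=1e4):
    vals = rng.uniform(1.0, scale, 3)
    return CompartmentState(r_s=float(vals[0]), r_i=float(vals[1]),
                            r_f=float(vals[2]))


def ivp_oracle(params, init, times, synthesis=True):
    """Independent brute-force integrator (tight-tolerance RK)."""
    from scipy.integrate import solve_ivp
    psyn = params.P_syn if synthesis else 0.0

    def rhs(t, x):
        ri, rs, rf = x
        return [params.k_end * rs - (params.k_rec + params.k_deg) * ri,
                psyn + params.k_rec * ri - (params.k_end + params.k_shed) * rs,
                params.k_shed * rs]

    times = np.asarray(times, float)
    sol = solve_ivp(rhs, (0.0, times[-1]), [init.r_i, init.r_s, init.r_f],
                    t_eval=times, rtol=1e-11, atol=1e-12, method="DOP853")
    return sol.y[1], sol.y[0], sol.y[2]  # r_s, r_i, r_f
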