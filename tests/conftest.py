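import numpy as np
import pytest

from cerebsim.model import canonical_model


@pytest.fixture(scope="session")
def model():
    """Canonical populations and projections (immutable; session-wide)."""
    return canonical_model()


@pytest.fixture(scope="session")
def pop_map(model):
    pops, _ = model
    return {p.name: p for p in pops}


@pytest.fixture(scope="session")
def proj_map(model):
    _, projs = model
    return {p.name: p for p in projs}


def lif_reference(params, inc_e, inc_i, dt=0.1, rtol=1e-9):
    """Continuous-time reference integration of the conductance LIF.

    Piecewise solution with scipy's adaptive solver between grid events:
    conductances jump by the per-step increments (normalized units) at step
    boundaries and decay exponentially in between; threshold crossings are
    located by event detection but spikes are resolved at step granularity,
    like the simulator; refractoriness is exact.  Returns spike steps.
    """
    from scipy.integrate import solve_ivp

    n_steps = len(inc_e)
    i_hat = params.i_offset * params.tau_m / params.cm

    def rhs(t, y, ge0, gi0, t0):
        ge = ge0 * np.exp(-(t - t0) / params.tau_syn_e)
        gi = gi0 * np.exp(-(t - t0) / params.tau_syn_i)
        return [((params.v_rest - y[0]) + ge * (0.0 - y[0])
                 + gi * (-90.0 - y[0]) + i_hat) / params.tau_m]

    def thresh(t, y, *args):
        return y[0] - params.v_thresh
    thresh.terminal = True
    thresh.direction = 1

    v = params.v_rest
    ge = gi = 0.0
    t_free = 0.0
    de = np.exp(-dt / params.tau_syn_e)
    di = np.exp(-dt / params.tau_syn_i)
    spike_steps = []
    for t in range(n_steps):
        t0, t1 = t * dt, (t + 1) * dt
        ge += inc_e[t]
        gi += inc_i[t]
        if t1 > t_free:
            ta = max(t0, t_free)
            ge_a = ge * np.exp(-(ta - t0) / params.tau_syn_e)
            gi_a = gi * np.exp(-(ta - t0) / params.tau_syn_i)
            if ta > t0:
                v = params.v_reset
            sol = solve_ivp(rhs, (ta, t1), [v], args=(ge_a, gi_a, ta),
                            events=thresh, rtol=rtol, atol=1e-12, max_step=dt)
            if sol.t_events[0].size:
                spike_steps.append(t)
                v = params.v_reset
                t_free = t1 + params.tau_refract
            else:
                v = sol.y[0, -1]
        ge *= de
        gi *= di
    return np.array(spike_steps)
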