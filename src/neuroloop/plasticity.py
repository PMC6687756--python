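"""Continuous-time temporal-difference machinery.

The critic activity z(t) should approximate the continuous-time value
function

    V(t) = integral_t^inf r(t') exp(-(t' - t) / tau_r) dt',

obtained by gradient descent on the objective E = (V - z)^2 / 2.  The
resulting three-factor rule is

    dw_j = eta * delta(t) * x_j(t) * Theta(z(t) - theta_post),

where delta(t) = dv/dt + r(t) - v(t)/tau_r is the reward-prediction
error.  The derivative is avoided with a two-point difference,

    delta(t) ~= (1/d - 1/tau_r) v(t) - (1/d) v(t - d) + r(t),

which is algebraically exact for linear v and is realized in the agent
as two critic->RPE connections, one instantaneous and one with delay d.

For discrete environments whose input tuning curves do not overlap, the
eligibility-delay variant evaluates pre- and postsynaptic activities a
short lag ``delta_t`` in the past, so that plasticity credits the
state-action pair that caused the current reward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NetworkState, heaviside

__all__ = [
    "TDParams",
    "RPEState",
    "discounted_value",
    "td_objective",
    "reward_prediction_error",
    "update_weight",
    "delayed_traces",
]


@dataclass
class TDParams:
    """Learning constants of the three-factor TD rule.

    eta : learning rate per network step (> 0)
    tau_r : reward discount time constant, ms (> d)
    d : delay of the second critic->RPE link, ms (> 0)
    theta_post : postsynaptic gate threshold
    delta_t : eligibility delay, ms (>= 0; 0 disables the variant)
    """

    eta: float
    tau_r: float
    d: float
    theta_post: float = 0.0
    delta_t: float = 0.0

    def __post_init__(self) -> None:
        if not (self.eta >= 0):
            raise ValueError("eta must be >= 0")
        if not (self.d > 0):
            raise ValueError("d must be > 0")
        if not (self.tau_r > self.d):
            raise ValueError("tau_r must exceed the RPE delay d")
        if self.delta_t < 0:
            raise ValueError("delta_t must be >= 0")


@dataclass
class RPEState:
    """Snapshot of the reward-prediction-error computation."""

    delta: float
    v_now: float
    v_delayed: float
    r: float


def discounted_value(reward_traj, tau_r: float, dt: float = 1.0) -> np.ndarray:
    """Exponentially discounted value of a regularly sampled reward trace.

    Computes V(t_k) = integral_{t_k}^inf r(t') exp(-(t'-t_k)/tau_r) dt'
    by backward recursion, treating r as piecewise constant over each
    step and zero beyond the end of the trace.  This is the test oracle
    for the value function; it is not used by the learning rule.
    """
    r = np.asarray(reward_traj, dtype=float)
    if r.size == 0:
        raise ValueError("empty reward trajectory")
    q = np.exp(-dt / tau_r)
    step_gain = tau_r * (1.0 - q)  # integral of the kernel over one step
    v = np.zeros_like(r)
    acc = 0.0
    for k in range(r.size - 1, -1, -1):
        acc = r[k] * step_gain + q * acc
        v[k] = acc
    return v


def td_objective(V: float, z: float) -> float:
    """Squared prediction error E = (V - z)^2 / 2 minimized by the critic."""
    return 0.5 * (float(V) - float(z)) ** 2


def reward_prediction_error(v_now: float, v_delayed: float, r: float,
                            p: TDParams) -> float:
    """Two-point RPE: delta = (1/d - 1/tau_r) v(t) - (1/d) v(t-d) + r(t)."""
    return (1.0 / p.d - 1.0 / p.tau_r) * v_now - v_delayed / p.d + r


def update_weight(w, x_pre, z_post, delta: float, p: TDParams,
                  w_min: float = -np.inf):
    """Three-factor update with a hard weight floor.

    ``w' = max(w_min, w + eta * delta * x_pre * Theta(z_post - theta_post))``.

    Broadcasts over arrays: for a projection onto several postsynaptic
    units pass ``w`` of shape (n_post, n_pre), ``x_pre`` of shape
    (n_pre,) and ``z_post`` of shape (n_post, 1).  Updates that are
    exactly zero (delta = 0 or sub-threshold gate) leave ``w`` untouched,
    including entries already below the floor.

    With ``p.delta_t > 0`` the caller supplies pre/post activities read
    ``delta_t`` earlier (see :func:`delayed_traces`); the rule itself is
    unchanged.
    """
    w = np.asarray(w, dtype=float)
    gate = heaviside(np.asarray(z_post, dtype=float) - p.theta_post)
    dw = p.eta * delta * np.asarray(x_pre, dtype=float) * gate
    out = np.where(dw != 0.0, np.maximum(w + dw, w_min), w)
    return float(out) if out.ndim == 0 else out


def delayed_traces(buffer: NetworkState, delta_t: float,
                   pre_slice=None, post_slice=None):
    """Pre/post activities recorded exactly ``delta_t`` ms before now.

    ``delta_t = 0`` returns the current activities.  Raises if the ring
    buffer is not deep enough.
    """
    steps = delta_t / buffer.dt
    k = int(round(steps))
    if abs(steps - k) > 1e-9:
        raise ValueError("delta_t must be an integer multiple of dt")
    z = buffer.lookup(k)
    pre = z if pre_slice is None else z[pre_slice]
    post = z if post_slice is None else z[post_slice]
    return pre, post
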