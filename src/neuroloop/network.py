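"""Noisy rate-neuron networks integrated on a fixed time grid.

The neuron model is a first-order stochastic rate equation

    tau dz_i/dt = -z_i + mu_i + f(h_i + ext_i - theta_i) + xi_i(t),

with ``h_i = sum_j w_ij z_j(t - delay_ij)`` the recurrent input field,
``ext_i`` an external drive, ``f`` either the identity or the
threshold-linear (relu) function, and ``xi_i`` Gaussian white noise of
amplitude ``sigma_xi``.  Time is in milliseconds throughout; activities
are dimensionless.

Integration uses the stochastic exponential-Euler scheme: the input is
treated as constant over a step of size ``dt``, the linear leak is
integrated exactly, and the noise increment is drawn with standard
deviation ``sigma_xi * sqrt((1 - exp(-2 dt / tau)) / 2)`` so that the
stationary distribution of a free noisy neuron is an Ornstein-Uhlenbeck
stationary distribution with std ``sigma_xi / sqrt(2)``, independent of
the step size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ACTIVATION_KINDS",
    "heaviside",
    "activation",
    "RateNeuronParams",
    "WeightMatrix",
    "NetworkState",
    "input_field",
    "step_network",
    "RateNetwork",
]

ACTIVATION_KINDS = ("linear", "threshold_linear")


def heaviside(x):
    """Strict Heaviside step: 1 where x > 0, else 0 (including x = 0).

    Accepts scalars or arrays; rejects non-finite input.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("heaviside: input must be finite")
    out = (arr > 0.0).astype(float)
    return float(out) if np.isscalar(x) or out.ndim == 0 else out


def activation(x, kind):
    """Apply the activation function ``f`` of the rate equation.

    ``linear``: f(x) = x.  ``threshold_linear``: f(x) = Theta(x) * x.
    """
    if kind == "linear":
        return np.asarray(x, dtype=float) if not np.isscalar(x) else float(x)
    if kind == "threshold_linear":
        arr = np.asarray(x, dtype=float)
        out = np.where(arr > 0.0, arr, 0.0)
        return float(out) if np.isscalar(x) or out.ndim == 0 else out
    raise ValueError(f"unknown activation kind: {kind!r}")


@dataclass
class RateNeuronParams:
    """Per-population constants of the rate equation.

    tau : membrane/rate time constant in ms (> 0)
    mu : baseline activity
    theta : input threshold, applied inside f as f(h + ext - theta)
    sigma_xi : intrinsic noise amplitude (>= 0)
    activation : "linear" or "threshold_linear"
    """

    tau: float
    mu: float = 0.0
    theta: float = 0.0
    sigma_xi: float = 0.0
    activation: str = "linear"

    def __post_init__(self) -> None:
        if not (self.tau > 0):
            raise ValueError("tau must be > 0")
        if self.sigma_xi < 0:
            raise ValueError("sigma_xi must be >= 0")
        if self.activation not in ACTIVATION_KINDS:
            raise ValueError(f"unknown activation kind: {self.activation!r}")


def _as_delay_steps(delay, dt: float):
    """Convert delays in ms to integer step counts, enforcing divisibility."""
    arr = np.asarray(delay, dtype=float)
    if np.any(arr < 0):
        raise ValueError("delays must be >= 0")
    steps = arr / dt
    rounded = np.rint(steps)
    if np.any(np.abs(steps - rounded) > 1e-9):
        raise ValueError(f"delay {delay!r} is not an integer multiple of dt={dt}")
    out = rounded.astype(int)
    return int(out) if out.ndim == 0 else out


@dataclass
class WeightMatrix:
    """Dense connection matrix source -> target.

    ``w[i, j]`` is the weight from source unit j to target unit i.
    ``delay`` is in ms, either a scalar (uniform) or an array per
    connection.  ``plastic`` marks entries subject to learning; plastic
    entries are kept >= ``w_min`` by :meth:`apply_floor` (called by the
    learning rule after every update).
    """

    w: np.ndarray
    delay: object = 0.0
    plastic: object = False
    w_min: float = -np.inf

    def __post_init__(self) -> None:
        self.w = np.array(self.w, dtype=float)
        if self.w.ndim != 2:
            raise ValueError("w must be a 2-d matrix (n_target, n_source)")
        d = np.asarray(self.delay, dtype=float)
        if d.ndim not in (0, 2):
            raise ValueError("delay must be a scalar or a (n_target, n_source) array")
        if d.ndim == 2 and d.shape != self.w.shape:
            raise ValueError("per-connection delay shape must match w")
        if np.any(d < 0):
            raise ValueError("delays must be >= 0")
        p = np.asarray(self.plastic)
        if p.ndim == 2 and p.shape != self.w.shape:
            raise ValueError("plastic mask shape must match w")

    @property
    def n_target(self) -> int:
        return self.w.shape[0]

    @property
    def n_source(self) -> int:
        return self.w.shape[1]

    @property
    def plastic_mask(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.plastic, dtype=bool), self.w.shape)

    def max_delay(self) -> float:
        return float(np.max(np.asarray(self.delay, dtype=float)))

    def delay_steps(self, dt: float):
        return _as_delay_steps(self.delay, dt)

    def apply_floor(self) -> None:
        mask = self.plastic_mask
        if mask.any():
            np.maximum(self.w, np.where(mask, self.w_min, -np.inf), out=self.w)


class NetworkState:
    """Activity vector plus a ring buffer of past activities.

    The buffer must be deep enough for the largest connection delay used
    anywhere in the network (checked at lookup time; requesting a longer
    lag than the configured depth is an error, not a resize).
    """

    def __init__(self, n: int, dt: float, depth: int = 1, z0=None):
        if dt <= 0:
            raise ValueError("dt must be > 0")
        if depth < 1:
            raise ValueError("history depth must be >= 1")
        self.n = int(n)
        self.dt = float(dt)
        self.t = 0.0
        self.depth = int(depth)
        self._history = np.zeros((self.depth, self.n))
        self._head = 0
        if z0 is not None:
            self._history[0] = np.asarray(z0, dtype=float)

    @property
    def z(self) -> np.ndarray:
        """Current activity vector (view into the ring buffer)."""
        return self._history[self._head]

    def push(self, z: np.ndarray) -> None:
        self._head = (self._head + 1) % self.depth
        self._history[self._head] = z
        self.t += self.dt

    def lookup(self, steps_back: int) -> np.ndarray:
        """Activity recorded exactly ``steps_back`` steps ago (0 = now)."""
        if steps_back < 0 or steps_back >= self.depth:
            raise ValueError(
                f"lag of {steps_back} steps exceeds history depth {self.depth}"
            )
        return self._history[(self._head - steps_back) % self.depth]


def input_field(weights: WeightMatrix, state: NetworkState) -> np.ndarray:
    """Weighted sum of presynaptic activities, sampled at t - delay.

    ``h_i = sum_j w_ij z_j(t - delay_ij)``.
    """
    if weights.n_source != state.n:
        raise ValueError(
            f"weight matrix expects {weights.n_source} sources, state has {state.n}"
        )
    steps = weights.delay_steps(state.dt)
    if np.ndim(steps) == 0:
        return weights.w @ state.lookup(int(steps))
    h = np.zeros(weights.n_target)
    for d in np.unique(steps):
        h += np.where(steps == d, weights.w, 0.0) @ state.lookup(int(d))
    return h


def _exp_euler(z, u, decay, noise_amp, rng):
    znew = u + (z - u) * decay
    if np.any(noise_amp > 0):
        znew = znew + noise_amp * rng.standard_normal(znew.shape)
    return znew


def step_network(
    state: NetworkState,
    params: RateNeuronParams,
    weights: WeightMatrix,
    ext,
    dt: float,
    rng: np.random.Generator | None = None,
) -> NetworkState:
    """Advance a homogeneous population by one stochastic exponential-Euler step.

    Drift toward ``mu + f(h + ext - theta)`` with exact leak integration;
    additive Gaussian noise increment with dt-invariant stationary
    statistics.  ``dt`` must equal the grid spacing of ``state``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if abs(dt - state.dt) > 1e-12:
        raise ValueError("dt must match the state's time grid")
    if params.sigma_xi > 0 and rng is None:
        raise ValueError("rng required when sigma_xi > 0")
    h = input_field(weights, state)
    u = params.mu + activation(h + np.asarray(ext, dtype=float) - params.theta,
                               params.activation)
    decay = np.exp(-dt / params.tau)
    noise_amp = params.sigma_xi * np.sqrt((1.0 - decay**2) / 2.0)
    state.push(_exp_euler(state.z, u, decay, noise_amp, rng))
    return state


@dataclass
class _Population:
    name: str
    start: int
    stop: int
    params: RateNeuronParams

    @property
    def sl(self) -> slice:
        return slice(self.start, self.stop)


@dataclass
class _Projection:
    src: _Population
    dst: _Population
    weights: WeightMatrix
    delay_steps: int = 0


class RateNetwork:
    """A heterogeneous network of rate-neuron populations with delayed projections.

    Populations are declared with :meth:`add_population`, connected with
    :meth:`connect`, then frozen with :meth:`build`.  The history ring
    buffer is sized from the maximum configured delay (plus an optional
    extra margin for eligibility-trace lookups); longer lags raise.

    Seeding: :meth:`build` takes one seed and derives one child stream
    per population (used only by populations with ``sigma_xi > 0``), so
    runs are bit-reproducible given (configuration, seed).
    """

    def __init__(self, dt: float = 1.0):
        if dt <= 0:
            raise ValueError("dt must be > 0")
        self.dt = float(dt)
        self.populations: dict[str, _Population] = {}
        self.projections: list[_Projection] = []
        self.state: NetworkState | None = None
        self._n = 0

    def add_population(self, name: str, n: int, params: RateNeuronParams) -> None:
        if self.state is not None:
            raise RuntimeError("network already built")
        if name in self.populations:
            raise ValueError(f"duplicate population {name!r}")
        if n < 1:
            raise ValueError("population size must be >= 1")
        self.populations[name] = _Population(name, self._n, self._n + n, params)
        self._n += n

    def connect(self, src: str, dst: str, weights: WeightMatrix) -> WeightMatrix:
        if self.state is not None:
            raise RuntimeError("network already built")
        s, d = self.populations[src], self.populations[dst]
        if weights.n_source != s.stop - s.start or weights.n_target != d.stop - d.start:
            raise ValueError("weight matrix shape does not match populations")
        steps = weights.delay_steps(self.dt)
        if np.ndim(steps) != 0:
            raise ValueError("RateNetwork projections use a uniform delay per "
                             "projection; split per-connection delays into "
                             "separate projections")
        self.projections.append(_Projection(s, d, weights, int(steps)))
        return weights

    def build(self, seed: int | None = None, extra_history_ms: float = 0.0) -> None:
        if self.state is not None:
            raise RuntimeError("network already built")
        extra = _as_delay_steps(extra_history_ms, self.dt)
        max_delay = max((p.delay_steps for p in self.projections), default=0)
        depth = max(max_delay, int(extra)) + 1
        self.state = NetworkState(self._n, self.dt, depth=depth)
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(len(self.populations))
        self._rngs = {}
        self._decay = np.zeros(self._n)
        self._noise_amp = np.zeros(self._n)
        self._mu = np.zeros(self._n)
        self._theta = np.zeros(self._n)
        for child, pop in zip(children, self.populations.values()):
            p = pop.params
            decay = np.exp(-self.dt / p.tau)
            self._decay[pop.sl] = decay
            self._noise_amp[pop.sl] = p.sigma_xi * np.sqrt((1.0 - decay**2) / 2.0)
            self._mu[pop.sl] = p.mu
            self._theta[pop.sl] = p.theta
            if p.sigma_xi > 0:
                self._rngs[pop.name] = np.random.default_rng(child)

    def step(self, ext: dict | np.ndarray | None = None) -> None:
        """Advance every population by one dt with external drive ``ext``.

        ``ext`` is either a full-length vector or a dict mapping
        population names to per-population drive vectors.
        """
        if self.state is None:
            raise RuntimeError("network not built")
        st = self.state
        full_ext = np.zeros(self._n)
        if ext is not None:
            if isinstance(ext, dict):
                for name, v in ext.items():
                    full_ext[self.populations[name].sl] = v
            else:
                full_ext[:] = ext
        h = np.zeros(self._n)
        for proj in self.projections:
            zsrc = st.lookup(proj.delay_steps)[proj.src.sl]
            h[proj.dst.sl] += proj.weights.w @ zsrc
        x = h + full_ext - self._theta
        u = np.empty(self._n)
        for pop in self.populations.values():
            seg = x[pop.sl]
            if pop.params.activation == "threshold_linear":
                seg = np.where(seg > 0.0, seg, 0.0)
            u[pop.sl] = pop.params.mu + seg
        z = u + (st.z - u) * self._decay
        for name, rng in self._rngs.items():
            sl = self.populations[name].sl
            z[sl] = z[sl] + self._noise_amp[sl] * rng.standard_normal(sl.stop - sl.start)
        st.push(z)

    def z(self, name: str) -> np.ndarray:
        """Current activity of a population (read-only view)."""
        return self.state.z[self.populations[name].sl]

    def lagged(self, name: str, lag_ms: float) -> np.ndarray:
        """Activity of a population recorded ``lag_ms`` ago."""
        steps = _as_delay_steps(lag_ms, self.dt)
        return self.state.lookup(int(steps))[self.populations[name].sl]
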