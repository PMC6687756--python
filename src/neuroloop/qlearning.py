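"""Q-learning baseline with MLP function approximation.

A single-hidden-layer perceptron (rectifying-linear hidden units) maps
the observation to one estimated Q-value per action.  Actions are
selected epsilon-greedily, transitions are stored in a replay memory
and sampled uniformly, and the semi-gradient of the squared TD error

    L = mean_b (r + gamma * max_a' Q(s', a') * (1 - done) - Q(s, a))^2

is applied with the ADAM optimizer.  The bootstrap target uses the
online network (no target network) and only the taken action's output
contributes per transition.  Observations are normalized to [-1, 1]
per dimension before the MLP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QNetParams",
    "QLearnParams",
    "ReplayBuffer",
    "AdamState",
    "init_qnet",
    "q_forward",
    "epsilon_greedy",
    "q_update",
    "q_gradients",
    "train_q_mountaincar",
]


@dataclass
class QNetParams:
    """Weights of the obs -> hidden (relu) -> n_actions network."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray

    @property
    def n_actions(self) -> int:
        return self.b2.shape[0]

    @property
    def hidden_size(self) -> int:
        return self.b1.shape[0]

    def copy(self) -> "QNetParams":
        return QNetParams(self.W1.copy(), self.b1.copy(),
                          self.W2.copy(), self.b2.copy())


@dataclass
class QLearnParams:
    """Discount, exploration schedule, and ADAM constants."""

    gamma: float = 0.99
    epsilon_start: float = 1.0
    epsilon_end: float = 0.05
    epsilon_decay_steps: int = 5000
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps_adam: float = 1e-8
    batch_size: int = 64

    def __post_init__(self) -> None:
        if not (0 < self.gamma <= 1):
            raise ValueError("gamma must be in (0, 1]")
        for e in (self.epsilon_start, self.epsilon_end):
            if not (0 <= e <= 1):
                raise ValueError("epsilon must be in [0, 1]")

    def epsilon_at(self, step: int) -> float:
        frac = min(1.0, step / max(1, self.epsilon_decay_steps))
        return self.epsilon_start + frac * (self.epsilon_end - self.epsilon_start)


class ReplayBuffer:
    """Fixed-capacity transition store with uniform sampling."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._data: list = []
        self._idx = 0

    def __len__(self) -> int:
        return len(self._data)

    def add(self, s, a, r, s_next, done) -> None:
        item = (np.asarray(s, dtype=float), int(a), float(r),
                np.asarray(s_next, dtype=float), bool(done))
        if len(self._data) < self.capacity:
            self._data.append(item)
        else:
            self._data[self._idx] = item
        self._idx = (self._idx + 1) % self.capacity

    def sample(self, batch_size: int, rng: np.random.Generator):
        if not self._data:
            raise ValueError("cannot sample from an empty replay buffer")
        idx = rng.integers(0, len(self._data), size=batch_size)
        s = np.stack([self._data[i][0] for i in idx])
        a = np.array([self._data[i][1] for i in idx])
        r = np.array([self._data[i][2] for i in idx])
        s2 = np.stack([self._data[i][3] for i in idx])
        d = np.array([self._data[i][4] for i in idx], dtype=float)
        return s, a, r, s2, d


@dataclass
class AdamState:
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)
    t: int = 0


def init_qnet(n_inputs: int, hidden: int, n_actions: int,
              rng: np.random.Generator) -> QNetParams:
    """He-style initialization for the relu hidden layer."""
    W1 = rng.normal(0, np.sqrt(2.0 / n_inputs), size=(hidden, n_inputs))
    W2 = rng.normal(0, np.sqrt(2.0 / hidden), size=(n_actions, hidden))
    return QNetParams(W1, np.zeros(hidden), W2, np.zeros(n_actions))


def q_forward(params: QNetParams, obs) -> np.ndarray:
    """Q-values for one observation or a batch (last axis = features)."""
    obs = np.asarray(obs, dtype=float)
    if obs.ndim == 1:
        if obs.shape[0] != params.W1.shape[1]:
            raise ValueError("observation dimension mismatch")
        hidden = np.maximum(0.0, params.W1 @ obs + params.b1)
        return params.W2 @ hidden + params.b2
    hidden = np.maximum(0.0, obs @ params.W1.T + params.b1)
    return hidden @ params.W2.T + params.b2


def epsilon_greedy(q, epsilon: float, rng: np.random.Generator) -> int:
    """Argmax with probability 1 - epsilon, uniform random otherwise."""
    q = np.asarray(q, dtype=float)
    if q.size == 0:
        raise ValueError("empty Q-value vector")
    if not (0 <= epsilon <= 1):
        raise ValueError("epsilon must be in [0, 1]")
    if epsilon > 0 and rng.random() < epsilon:
        return int(rng.integers(0, q.size))
    return int(np.flatnonzero(q == q.max())[0])


def q_gradients(params: QNetParams, batch, gamma: float) -> tuple[dict, float]:
    """Semi-gradient of the mean squared TD error over a batch.

    Returns ({'W1','b1','W2','b2'}, loss).  The bootstrap term is
    treated as a constant (no gradient through the max).
    """
    s, a, r, s2, done = batch
    B = s.shape[0]
    pre = s @ params.W1.T + params.b1
    hidden = np.maximum(0.0, pre)
    q = hidden @ params.W2.T + params.b2
    q_next = q_forward(params, s2)
    target = r + gamma * q_next.max(axis=1) * (1.0 - done)
    q_taken = q[np.arange(B), a]
    err = q_taken - target
    loss = float(np.mean(err**2))
    # dL/dq only on the taken action's output
    dq = np.zeros_like(q)
    dq[np.arange(B), a] = 2.0 * err / B
    gW2 = dq.T @ hidden
    gb2 = dq.sum(axis=0)
    dh = (dq @ params.W2) * (pre > 0)
    gW1 = dh.T @ s
    gb1 = dh.sum(axis=0)
    return {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}, loss


def q_update(params: QNetParams, batch, p: QLearnParams,
             adam: AdamState | None = None) -> tuple[QNetParams, float]:
    """One ADAM step on the TD loss; returns (new params, loss)."""
    if batch[0].shape[0] == 0:
        raise ValueError("empty batch")
    adam = adam if adam is not None else AdamState()
    grads, loss = q_gradients(params, batch, p.gamma)
    adam.t += 1
    new = params.copy()
    for name, g in grads.items():
        m = adam.m.get(name, np.zeros_like(g))
        v = adam.v.get(name, np.zeros_like(g))
        m = p.beta1 * m + (1 - p.beta1) * g
        v = p.beta2 * v + (1 - p.beta2) * g**2
        adam.m[name], adam.v[name] = m, v
        mhat = m / (1 - p.beta1**adam.t)
        vhat = v / (1 - p.beta2**adam.t)
        arr = getattr(new, name)
        arr -= p.lr * mhat / (np.sqrt(vhat) + p.eps_adam)
    return new, loss


def _normalize(obs_values: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    low, high = bounds[:, 0], bounds[:, 1]
    return 2.0 * (obs_values - low) / (high - low) - 1.0


def train_q_mountaincar(env, p: QLearnParams, hidden: int = 64,
                        buffer_capacity: int = 20000,
                        n_episodes: int = 30,
                        max_episode_steps: int = 3000,
                        updates_per_step: int = 1,
                        seed: int | None = None) -> tuple[QNetParams, list]:
    """Train the baseline on a MountainCar-protocol environment.

    Returns the trained parameters and the per-episode reward curve.
    """
    rng = np.random.default_rng(seed)
    bounds = np.asarray(env.observation_bounds, dtype=float)
    params = init_qnet(bounds.shape[0], hidden, env.n_actions, rng)
    buffer = ReplayBuffer(buffer_capacity)
    adam = AdamState()
    returns = []
    global_step = 0
    for _ in range(n_episodes):
        obs = env.reset()
        s = _normalize(obs.values, bounds)
        total = 0.0
        for _ in range(max_episode_steps):
            eps = p.epsilon_at(global_step)
            a = epsilon_greedy(q_forward(params, s), eps, rng)
            res = env.step(a)
            s2 = _normalize(res.observation.values, bounds)
            buffer.add(s, a, res.reward, s2, res.done)
            total += res.reward
            s = s2
            global_step += 1
            if len(buffer) >= p.batch_size:
                for _ in range(updates_per_step):
                    params, _ = q_update(params, buffer.sample(p.batch_size, rng),
                                         p, adam)
            if res.done:
                break
        returns.append(total)
    return params, returns
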