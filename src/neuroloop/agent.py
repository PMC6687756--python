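"""The rate-neuron actor-critic agent.

Architecture: a place-cell input layer projects through plastic weights
both to a single critic unit (state value) and to a population of actor
units arranged in a winner-take-all (WTA) circuit (one unit per
action).  The critic projects twice to a reward-prediction-error (RPE)
unit — once instantaneously with weight (1/d - 1/tau_r) and once with
delay d and weight -1/d — which also receives the environment reward as
external input, so that its activity tracks the two-point TD error.
The RPE activity gates and signs the three-factor updates of both
plastic projections; the selected action is the index of the most
active actor unit.

Actor units receive additive input noise (a dedicated seeded stream,
distinct from the intrinsic sigma_xi) so that action selection explores
when the feedforward drives are uninformative; a minimal weight on the
input->actor projection guarantees that no action is ever permanently
ruled out.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .coding import (DiscreteEncoderSpec, Observation, PlaceCellLayout,
                     argmax_decode, encode, encode_discrete)
from .network import RateNetwork, RateNeuronParams, WeightMatrix
from .plasticity import TDParams, update_weight

__all__ = [
    "WTASpec",
    "AgentConfig",
    "PolicyValueMap",
    "build_wta_weights",
    "build_agent",
    "agent_step",
    "extract_policy_value",
    "Agent",
]


@dataclass
class WTASpec:
    """Recurrent actor connectivity: short-range excitation, long-range inhibition.

    The distance between actor units reflects the similarity of the
    actions they encode: ``line`` for ordered action sets (e.g. the three
    MountainCar accelerations), ``ring`` for cyclic ones (the four
    FrozenLake compass directions).
    """

    exc_strength: float = 0.05
    inh_strength: float = 0.6
    metric: str = "line"


@dataclass
class AgentConfig:
    """Everything needed to build the actor-critic deterministically."""

    encoder: object  # PlaceCellLayout | DiscreteEncoderSpec
    n_actions: int
    td: TDParams
    wta: WTASpec = field(default_factory=WTASpec)
    dt: float = 1.0
    input_params: RateNeuronParams = field(
        default_factory=lambda: RateNeuronParams(tau=2.0, activation="threshold_linear"))
    actor_params: RateNeuronParams = field(
        default_factory=lambda: RateNeuronParams(tau=10.0, activation="linear"))
    critic_params: RateNeuronParams = field(
        default_factory=lambda: RateNeuronParams(tau=5.0, activation="linear"))
    rpe_params: RateNeuronParams = field(
        default_factory=lambda: RateNeuronParams(tau=0.5, activation="linear"))
    actor_noise: float = 0.3
    w_init_actor: float = 0.05
    w_min_actor: float = 0.05
    w_init_jitter: float = 0.02
    w_init_critic: float = 0.0
    w_min_critic: float = -100.0
    critic_theta_post: float = -1e9  # gate effectively open for the critic
    # reward enters the RPE unit as a rate: external input is
    # reward_gain * r, held constant between environment steps.  With
    # reward_gain = 1 / env_step_interval the value of a state one step
    # before a unit reward is ~1 regardless of the interval length.
    reward_gain: float = 1.0
    # exploration noise is redrawn every actor_noise_interval ms and
    # held in between (None: fresh draw every network step); holding it
    # over one environment interval keeps the within-interval winner --
    # and therefore the plasticity gate -- aligned with the action that
    # is actually forwarded to the environment
    actor_noise_interval: float | None = None
    eta_actor: float | None = None   # None: same learning rate as the critic
    tie_rule: str = "lowest_index"

    def __post_init__(self) -> None:
        if self.n_actions < 2:
            raise ValueError("need at least 2 actions")
        if self.w_init_actor < self.w_min_actor:
            raise ValueError("initial actor weight must be >= w_min")
        if self.w_init_critic < self.w_min_critic:
            raise ValueError("initial critic weight must be >= w_min")

    @property
    def n_inputs(self) -> int:
        if isinstance(self.encoder, PlaceCellLayout):
            return self.encoder.n_cells
        return self.encoder.n_states


@dataclass
class PolicyValueMap:
    """Per-state value and preferred action of a trained agent."""

    values: np.ndarray
    actions: np.ndarray


def build_wta_weights(n_actions: int, exc: float, inh: float,
                      metric: str = "line") -> WeightMatrix:
    """Symmetric WTA recurrence: +exc for self/nearest neighbors, -inh otherwise."""
    if n_actions < 2:
        raise ValueError("WTA needs at least 2 units")
    if not (exc > 0 and inh > 0):
        raise ValueError("exc and inh must be > 0")
    if metric not in ("line", "ring"):
        raise ValueError(f"unknown metric: {metric!r}")
    idx = np.arange(n_actions)
    dist = np.abs(idx[:, None] - idx[None, :])
    if metric == "ring":
        dist = np.minimum(dist, n_actions - dist)
    w = np.where(dist <= 1, exc, -inh)
    return WeightMatrix(w=w)


class Agent:
    """A built actor-critic network plus its learning state."""

    def __init__(self, cfg: AgentConfig, seed: int | None = None):
        self.cfg = cfg
        ss = np.random.SeedSequence(seed)
        net_seed, noise_seed, init_seed, tie_seed = ss.spawn(4)
        self._noise_rng = np.random.default_rng(noise_seed)
        self._tie_rng = np.random.default_rng(tie_seed)
        init_rng = np.random.default_rng(init_seed)

        n_in, n_act = cfg.n_inputs, cfg.n_actions
        td = cfg.td
        net = RateNetwork(dt=cfg.dt)
        net.add_population("input", n_in, cfg.input_params)
        net.add_population("actor", n_act, cfg.actor_params)
        net.add_population("critic", 1, cfg.critic_params)
        net.add_population("rpe", 1, cfg.rpe_params)

        wc = cfg.w_init_critic + np.zeros((1, n_in))
        self.w_critic = net.connect("input", "critic", WeightMatrix(
            w=wc, plastic=True, w_min=cfg.w_min_critic))
        wa = cfg.w_init_actor + cfg.w_init_jitter * init_rng.random((n_act, n_in))
        self.w_actor = net.connect("input", "actor", WeightMatrix(
            w=wa, plastic=True, w_min=cfg.w_min_actor))
        net.connect("actor", "actor", build_wta_weights(
            n_act, cfg.wta.exc_strength, cfg.wta.inh_strength, cfg.wta.metric))
        # the two critic->RPE links realizing the two-point TD difference
        net.connect("critic", "rpe", WeightMatrix(
            w=np.array([[1.0 / td.d - 1.0 / td.tau_r]])))
        net.connect("critic", "rpe", WeightMatrix(
            w=np.array([[-1.0 / td.d]]), delay=td.d))
        net.build(seed=int(net_seed.generate_state(1)[0]),
                  extra_history_ms=max(td.d, td.delta_t))
        self.net = net
        self._td_critic = replace(td, theta_post=cfg.critic_theta_post)
        self._td_actor = (td if cfg.eta_actor is None
                          else replace(td, eta=cfg.eta_actor))
        if cfg.actor_noise_interval is None:
            self._noise_hold = 1
        else:
            ratio = cfg.actor_noise_interval / cfg.dt
            if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
                raise ValueError("actor_noise_interval must be a positive "
                                 "integer multiple of dt")
            self._noise_hold = int(round(ratio))
        self._noise_sample = np.zeros(cfg.n_actions)
        self._n_steps = 0

    # -- encoding ----------------------------------------------------------
    def encode_observation(self, obs: Observation | None) -> np.ndarray:
        """Input-layer drive for an observation; None means zero drive."""
        enc = self.cfg.encoder
        if obs is None:
            return np.zeros(self.cfg.n_inputs)
        if isinstance(enc, PlaceCellLayout):
            return encode(obs, enc)
        return encode_discrete(obs.discrete_index, enc.n_states, enc.peak)

    # -- closed-loop interface ---------------------------------------------
    def step(self, obs: Observation | None, reward: float,
             learn: bool = True) -> int:
        """One network step: encode, integrate, learn, decode an action.

        ``learn=False`` freezes the plastic projections for this step;
        the closed loop uses it right after an episode reset, while the
        two-point RPE window still straddles the value discontinuity of
        the reset (which carries no reward information).
        """
        cfg = self.cfg
        ext = {"input": self.encode_observation(obs),
               "rpe": cfg.reward_gain * reward}
        if cfg.actor_noise > 0:
            if self._n_steps % self._noise_hold == 0:
                self._noise_sample = (cfg.actor_noise *
                                      self._noise_rng.standard_normal(
                                          cfg.n_actions))
            ext["actor"] = self._noise_sample
        net = self.net
        net.step(ext)
        delta = float(net.z("rpe")[0])
        td = cfg.td
        if learn and td.eta > 0 and delta != 0.0:
            x = net.lagged("input", td.delta_t)
            z_c = net.lagged("critic", td.delta_t)
            z_a = net.lagged("actor", td.delta_t)
            self.w_critic.w[:] = update_weight(
                self.w_critic.w, x, z_c[:, None], delta, self._td_critic,
                self.w_critic.w_min)
            self.w_actor.w[:] = update_weight(
                self.w_actor.w, x, z_a[:, None], delta, self._td_actor,
                self.w_actor.w_min)
        self._n_steps += 1
        return argmax_decode(net.z("actor"), cfg.tie_rule, self._tie_rng)

    # -- read-outs ----------------------------------------------------------
    def value_drive(self, obs: Observation) -> float:
        """Critic drive (input activity . critic weights), no dynamics."""
        x = self.encode_observation(obs)
        return float((self.w_critic.w @ x)[0])

    def actor_drive(self, obs: Observation) -> np.ndarray:
        x = self.encode_observation(obs)
        return self.w_actor.w @ x

    @property
    def delta(self) -> float:
        return float(self.net.z("rpe")[0])


def build_agent(cfg: AgentConfig, seed: int | None = None) -> Agent:
    """Instantiate the full architecture; deterministic given (cfg, seed)."""
    return Agent(cfg, seed)


def agent_step(agent: Agent, obs: Observation | None, reward: float,
               dt: float | None = None, learn: bool = True) -> int:
    """Advance the agent by one network step and return the decoded action."""
    if dt is not None and abs(dt - agent.cfg.dt) > 1e-12:
        raise ValueError("dt must match the agent's configured time grid")
    return agent.step(obs, reward, learn=learn)


def extract_policy_value(agent: Agent, states) -> PolicyValueMap:
    """Value and preferred action per state, without learning side effects.

    Value is the critic's feedforward drive for the state's input
    activity; the preferred action is the argmax over the actor drive.
    """
    values, actions = [], []
    for obs in states:
        values.append(agent.value_drive(obs))
        actions.append(int(np.argmax(agent.actor_drive(obs))))
    return PolicyValueMap(values=np.array(values), actions=np.array(actions))
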