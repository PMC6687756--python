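"""Closed-loop driver and publish-subscribe environment bridge.

The loop co-steps an agent and an environment on two time grids: the
network evolves every ``network_dt`` ms while the environment advances
every ``env_step_interval`` ms (an integer multiple).  The decoded
action is forwarded to the environment only at environment-step
boundaries, and the observation and reward returned by the environment
are held constant (zero-order hold) for the following interval.  When
an episode ends the environment is reset after a break of configurable
duration during which the network keeps evolving with zero external
drive (plasticity stays enabled).

The bridge exposes an environment over plain TCP sockets with
line-delimited JSON messages, mirroring a publish-subscribe layout:
four concurrent workers (environment stepper, action subscriber,
observation publisher, reward publisher) coupled through latest-value
buffers (new messages overwrite old ones).  Wall-clock pacing is
optional; in the default *lockstep* handshake mode the stepper performs
exactly one environment step per received action message and the
publishers emit exactly one observation and one reward per step, tagged
with the action's sequence number, so that training through the bridge
is bit-identical to training in-process.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import socket
import threading
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agent import Agent, agent_step
from .coding import Observation
from .environments import StepResult

__all__ = [
    "LoopConfig",
    "EpisodeLog",
    "run_closed_loop",
    "EnvMessage",
    "MessageError",
    "encode_message",
    "decode_message",
    "EnvBridge",
    "serve_env",
    "RemoteEnv",
    "config_fingerprint",
]

MESSAGE_KINDS = ("observation", "reward", "action")


def config_fingerprint(obj) -> str:
    """Stable hash of a (nested dataclass / dict) configuration."""

    def unpack(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {"__type__": type(o).__name__,
                    **{k: unpack(v) for k, v in dataclasses.asdict(o).items()}}
        if isinstance(o, dict):
            return {k: unpack(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [unpack(v) for v in o]
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return o

    blob = json.dumps(unpack(obj), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Closed loop
# ---------------------------------------------------------------------------

@dataclass
class LoopConfig:
    """Timing and budget of a closed-loop run (times in ms)."""

    network_dt: float = 1.0
    env_step_interval: float = 10.0
    episode_break: float = 50.0
    max_env_steps: int | None = None
    max_episodes: int | None = None
    max_episode_steps: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        ratio = self.env_step_interval / self.network_dt
        if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
            raise ValueError(
                "env_step_interval must be a positive integer multiple of network_dt")
        if self.episode_break < 0:
            raise ValueError("episode_break must be >= 0")
        if self.max_env_steps is None and self.max_episodes is None:
            raise ValueError("set max_env_steps and/or max_episodes")

    @property
    def steps_per_env_step(self) -> int:
        return int(round(self.env_step_interval / self.network_dt))

    @property
    def break_steps(self) -> int:
        return int(round(self.episode_break / self.network_dt))


@dataclass
class EpisodeLog:
    """Time-indexed record of a closed-loop run.

    Per environment step: time (ms, network clock), observation, the
    action forwarded, the reward returned, the episode index, and
    optionally unit activities.  Per episode: total reward.
    """

    t: list = field(default_factory=list)
    obs: list = field(default_factory=list)
    action: list = field(default_factory=list)
    reward: list = field(default_factory=list)
    episode: list = field(default_factory=list)
    activities: list = field(default_factory=list)
    episode_returns: list = field(default_factory=list)
    n_network_steps: int = 0
    n_env_steps: int = 0
    seed: int | None = None
    config_hash: str = ""

    def append(self, t, obs, action, reward, episode, activity=None) -> None:
        self.t.append(float(t))
        self.obs.append(obs)
        self.action.append(int(action))
        self.reward.append(float(reward))
        self.episode.append(int(episode))
        if activity is not None:
            self.activities.append(activity)
        self.n_env_steps += 1

    def episode_totals(self) -> list:
        """Recompute per-episode reward sums from the step records."""
        totals: dict[int, float] = {}
        for ep, r in zip(self.episode, self.reward):
            totals[ep] = totals.get(ep, 0.0) + r
        return [totals[k] for k in sorted(totals)]

    def total_reward(self) -> float:
        return float(sum(self.reward))

    def to_dataframe(self) -> pd.DataFrame:
        def obs_repr(o):
            if isinstance(o, Observation):
                return (o.discrete_index if o.discrete_index is not None
                        else tuple(o.values))
            return o
        return pd.DataFrame({
            "t": self.t,
            "obs": [obs_repr(o) for o in self.obs],
            "action": self.action,
            "reward": self.reward,
            "episode": self.episode,
        })

    def summary(self) -> dict:
        return {
            "n_env_steps": self.n_env_steps,
            "n_network_steps": self.n_network_steps,
            "n_episodes": len(self.episode_returns),
            "episode_returns": list(self.episode_returns),
            "total_reward": self.total_reward(),
            "seed": self.seed,
            "config_hash": self.config_hash,
        }

    def __eq__(self, other) -> bool:
        if not isinstance(other, EpisodeLog):
            return NotImplemented

        def obs_key(o):
            if isinstance(o, Observation):
                return (None if o.values is None else tuple(o.values),
                        o.discrete_index)
            return o
        return (
            self.t == other.t
            and [obs_key(o) for o in self.obs] == [obs_key(o) for o in other.obs]
            and self.action == other.action
            and self.reward == other.reward
            and self.episode == other.episode
            and self.episode_returns == other.episode_returns
            and self.n_network_steps == other.n_network_steps
            and self.n_env_steps == other.n_env_steps
        )


def run_closed_loop(agent: Agent | None, env, cfg: LoopConfig,
                    policy=None, record_activities: bool = False) -> EpisodeLog:
    """Drive the agent-environment cycle until a budget is exhausted.

    ``policy``, if given, overrides the agent's decoded action (the
    network still steps and learns; used for scripted or fixed-policy
    runs).  With ``agent=None`` a policy is required and only the
    environment is stepped.
    """
    if agent is None and policy is None:
        raise ValueError("need an agent, a policy, or both")
    if agent is not None and abs(agent.cfg.dt - cfg.network_dt) > 1e-12:
        raise ValueError("agent dt does not match loop network_dt")
    log = EpisodeLog(seed=cfg.seed, config_hash=config_fingerprint(cfg))
    if cfg.max_episodes is not None and cfg.max_episodes <= 0:
        return log
    # after a reset, the two-point RPE window briefly straddles the value
    # discontinuity of the teleport back to the start; those deltas carry
    # no reward information, so plasticity pauses until the window (plus
    # the critic's settling time) has cleared the boundary
    if agent is not None:
        td = agent.cfg.td
        post_reset_frozen = int(np.ceil(
            (td.d + 3.0 * agent.cfg.critic_params.tau) / cfg.network_dt))
    else:
        post_reset_frozen = 0
    frozen = post_reset_frozen
    obs = env.reset()
    reward = 0.0
    episode = 0
    ep_return = 0.0
    ep_steps = 0
    action = 0
    while True:
        if cfg.max_env_steps is not None and log.n_env_steps >= cfg.max_env_steps:
            break
        if agent is not None:
            for _ in range(cfg.steps_per_env_step):
                action = agent_step(agent, obs, reward, learn=frozen <= 0)
                frozen -= 1
                log.n_network_steps += 1
        if policy is not None:
            action = policy(obs)
        res: StepResult = env.step(action)
        log.append(t=log.n_network_steps * cfg.network_dt, obs=obs,
                   action=action, reward=res.reward, episode=episode,
                   activity=(np.array(agent.net.state.z)
                             if record_activities and agent is not None else None))
        ep_return += res.reward
        ep_steps += 1
        obs, reward = res.observation, res.reward
        truncated = (cfg.max_episode_steps is not None
                     and ep_steps >= cfg.max_episode_steps)
        if res.done or truncated:
            log.episode_returns.append(ep_return)
            ep_return = 0.0
            ep_steps = 0
            episode += 1
            if agent is not None:
                # deliver the terminal observation and reward for one
                # environment interval (the reward buffer holds the last
                # value until the break starts), then evolve freely
                for _ in range(cfg.steps_per_env_step):
                    agent_step(agent, obs, reward)
                    log.n_network_steps += 1
                for _ in range(cfg.break_steps):
                    agent_step(agent, None, 0.0)
                    log.n_network_steps += 1
            if cfg.max_episodes is not None and episode >= cfg.max_episodes:
                break
            obs = env.reset()
            reward = 0.0
            frozen = post_reset_frozen
    return log


# ---------------------------------------------------------------------------
# JSON messages
# ---------------------------------------------------------------------------

class MessageError(ValueError):
    """Raised on malformed bridge messages; names the offending field."""


@dataclass
class EnvMessage:
    """One observation / reward / action message (schema version 1).

    ``payload`` is a real vector (continuous), or a single number
    (scalar reward / discrete index); ``dim`` declares its length and
    must match.  ``timestamp`` is a free clock; in lockstep mode it
    carries the handshake sequence number.  ``done`` marks terminal
    environment steps on the reward channel.
    """

    kind: str
    payload: object
    dim: int
    timestamp: float = 0.0
    done: bool = False

    def __post_init__(self) -> None:
        if self.kind not in MESSAGE_KINDS:
            raise MessageError(f"field 'kind': unknown value {self.kind!r}")
        n = len(self.payload) if isinstance(self.payload, (list, tuple)) else 1
        if n != self.dim:
            raise MessageError(
                f"field 'dim': declared {self.dim}, payload has length {n}")

    def scalar(self) -> float:
        return float(self.payload[0] if isinstance(self.payload, (list, tuple))
                     else self.payload)


def encode_message(msg: EnvMessage) -> bytes:
    payload = msg.payload
    if isinstance(payload, np.ndarray):
        payload = payload.tolist()
    if isinstance(payload, (np.integer, np.floating)):
        payload = payload.item()
    return json.dumps({
        "kind": msg.kind, "dim": msg.dim, "payload": payload,
        "timestamp": msg.timestamp, "done": msg.done,
    }).encode()


def decode_message(raw: bytes) -> EnvMessage:
    try:
        d = json.loads(raw.decode())
    except (UnicodeDecodeError, json.JSONDecodeError) as e:
        raise MessageError(f"not valid JSON: {e}") from None
    if not isinstance(d, dict):
        raise MessageError("message must be a JSON object")
    for name in ("kind", "dim", "payload"):
        if name not in d:
            raise MessageError(f"field {name!r}: missing")
    if not isinstance(d["dim"], int):
        raise MessageError("field 'dim': must be an integer")
    return EnvMessage(kind=d["kind"], payload=d["payload"], dim=d["dim"],
                      timestamp=float(d.get("timestamp", 0.0)),
                      done=bool(d.get("done", False)))


def _obs_message(obs: Observation, timestamp: float) -> EnvMessage:
    if obs.discrete_index is not None:
        return EnvMessage("observation", int(obs.discrete_index), 1, timestamp)
    vals = [float(v) for v in obs.values]
    return EnvMessage("observation", vals, len(vals), timestamp)


def _obs_from_message(msg: EnvMessage) -> Observation:
    if msg.dim == 1 and isinstance(msg.payload, int):
        return Observation(discrete_index=msg.payload)
    return Observation(values=np.atleast_1d(np.asarray(msg.payload, dtype=float)))


# ---------------------------------------------------------------------------
# Bridge
# ---------------------------------------------------------------------------

class _LatestValue:
    """Overwrite-on-write buffer shared between bridge workers."""

    def __init__(self, initial=None):
        self._lock = threading.Lock()
        self._value = initial
        self._seq = 0
        self._event = threading.Event()

    def set(self, value) -> int:
        with self._lock:
            self._value = value
            self._seq += 1
            self._event.set()
            return self._seq

    def get(self):
        with self._lock:
            return self._value, self._seq

    def wait_newer(self, seq: int, timeout: float) -> bool:
        deadline = time.monotonic() + timeout
        while True:
            with self._lock:
                if self._seq > seq:
                    return True
                self._event.clear()
            remaining = deadline - time.monotonic()
            if remaining <= 0:
                return False
            self._event.wait(min(remaining, 0.05))


@dataclass
class BridgeConfig:
    """Bridge behavior; wall-clock intervals in seconds."""

    lockstep: bool = True
    default_action: int = 0
    step_interval: float = 0.01
    publish_interval: float = 0.01
    episode_break: float = 0.0
    auto_reset: bool = True


class _Channel:
    """One listening TCP socket plus its connected peers."""

    def __init__(self, host: str, port: int):
        self.server = socket.socket(socket.AF_INET, socket.SOCK_STREAM)
        self.server.setsockopt(socket.SOL_SOCKET, socket.SO_REUSEADDR, 1)
        self.server.bind((host, port))
        self.server.listen(4)
        self.server.settimeout(0.05)
        self.host, self.port = self.server.getsockname()
        self.peers: list[socket.socket] = []
        self._lock = threading.Lock()

    def accept_pending(self) -> None:
        try:
            conn, _ = self.server.accept()
        except (socket.timeout, OSError):
            return
        conn.settimeout(0.05)
        with self._lock:
            self.peers.append(conn)

    def broadcast(self, line: bytes) -> None:
        with self._lock:
            dead = []
            for p in self.peers:
                try:
                    p.sendall(line + b"\n")
                except OSError:
                    dead.append(p)
            for p in dead:
                self.peers.remove(p)

    def close(self) -> None:
        with self._lock:
            for p in self.peers:
                try:
                    p.close()
                except OSError:
                    pass
            self.peers.clear()
        try:
            self.server.close()
        except OSError:
            pass


class EnvBridge:
    """Serve an environment over three TCP channels with four workers.

    Workers: (i) environment stepper, (ii) action subscriber,
    (iii) observation publisher, (iv) reward publisher.  All exchange
    data exclusively through latest-value buffers.
    """

    def __init__(self, env, host: str = "127.0.0.1", ports=(0, 0, 0),
                 cfg: BridgeConfig | None = None):
        self.env = env
        self.cfg = cfg or BridgeConfig()
        self._action_ch = _Channel(host, ports[0])
        self._obs_ch = _Channel(host, ports[1])
        self._reward_ch = _Channel(host, ports[2])
        self._action_buf = _LatestValue((self.cfg.default_action, 0.0))
        self._obs_buf = _LatestValue()
        self._reward_buf = _LatestValue()
        self._stop = threading.Event()
        self._threads: list[threading.Thread] = []
        self.dropped_messages = 0

    @property
    def endpoints(self) -> dict:
        return {"action": (self._action_ch.host, self._action_ch.port),
                "observation": (self._obs_ch.host, self._obs_ch.port),
                "reward": (self._reward_ch.host, self._reward_ch.port)}

    # -- workers -----------------------------------------------------------
    def _action_subscriber(self) -> None:
        buffers: dict[socket.socket, bytes] = {}
        while not self._stop.is_set():
            self._action_ch.accept_pending()
            with self._action_ch._lock:
                peers = list(self._action_ch.peers)
            for p in peers:
                try:
                    chunk = p.recv(4096)
                except socket.timeout:
                    continue
                except OSError:
                    continue
                if not chunk:
                    continue
                buf = buffers.get(p, b"") + chunk
                while b"\n" in buf:
                    line, buf = buf.split(b"\n", 1)
                    self._handle_action_line(line)
                buffers[p] = buf

    def _handle_action_line(self, line: bytes) -> None:
        if not line.strip():
            return
        try:
            d = json.loads(line.decode())
        except (UnicodeDecodeError, json.JSONDecodeError):
            self.dropped_messages += 1
            return
        if isinstance(d, dict) and d.get("kind") == "reset":
            self._action_buf.set(("__reset__", float(d.get("timestamp", 0.0))))
            return
        try:
            msg = decode_message(line)
        except MessageError:
            self.dropped_messages += 1
            return
        if msg.kind != "action":
            self.dropped_messages += 1
            return
        self._action_buf.set((int(msg.scalar()), msg.timestamp))

    def _publish_state(self, obs: Observation, reward: float, done: bool,
                       stamp: float) -> None:
        self._obs_buf.set(_obs_message(obs, stamp))
        self._reward_buf.set(EnvMessage("reward", float(reward), 1, stamp, done))

    def _stepper_loop(self) -> None:
        cfg = self.cfg
        if not cfg.lockstep:
            # free-running mode primes the buffers immediately; in
            # lockstep the first client message (normally a reset)
            # drives the first state publication, so that the server
            # consumes environment randomness exactly as an in-process
            # run would
            obs = self.env.reset()
            self._publish_state(obs, 0.0, False, 0.0)
        _, last_seq = self._action_buf.get()
        while not self._stop.is_set():
            if cfg.lockstep:
                if not self._action_buf.wait_newer(last_seq, timeout=0.1):
                    continue
            (action, stamp), last_seq = self._action_buf.get()
            if action == "__reset__":
                obs = self.env.reset()
                self._publish_state(obs, 0.0, False, stamp)
                if not cfg.lockstep:
                    time.sleep(cfg.step_interval)
                continue
            res = self.env.step(int(action))
            self._publish_state(res.observation, res.reward, res.done, stamp)
            if res.done and cfg.auto_reset and not cfg.lockstep:
                if cfg.episode_break > 0:
                    self._stop.wait(cfg.episode_break)
                obs = self.env.reset()
                self._publish_state(obs, 0.0, False, stamp)
            if not cfg.lockstep:
                self._stop.wait(cfg.step_interval)

    def _publisher(self, channel: _Channel, buf: _LatestValue) -> None:
        last_sent = 0
        while not self._stop.is_set():
            channel.accept_pending()
            value, seq = buf.get()
            if value is not None and seq > last_sent:
                channel.broadcast(encode_message(value))
                last_sent = seq
            elif not self.cfg.lockstep and value is not None:
                # free-running publishers re-send the latest value at
                # their own interval
                channel.broadcast(encode_message(value))
                self._stop.wait(self.cfg.publish_interval)

    # -- lifecycle ---------------------------------------------------------
    def start(self) -> "EnvBridge":
        workers = [self._stepper_loop, self._action_subscriber,
                   lambda: self._publisher(self._obs_ch, self._obs_buf),
                   lambda: self._publisher(self._reward_ch, self._reward_buf)]
        for fn in workers:
            th = threading.Thread(target=fn, daemon=True)
            th.start()
            self._threads.append(th)
        return self

    def stop(self, timeout: float = 2.0) -> None:
        self._stop.set()
        for th in self._threads:
            th.join(timeout)
        for ch in (self._action_ch, self._obs_ch, self._reward_ch):
            ch.close()

    def __enter__(self):
        return self.start()

    def __exit__(self, *exc):
        self.stop()


def serve_env(env, endpoints=None, cfg: BridgeConfig | None = None) -> EnvBridge:
    """Start a bridge serving ``env``; returns the running bridge.

    ``endpoints`` is (host, action_port, obs_port, reward_port); omit
    for ephemeral ports on localhost (read them from
    ``bridge.endpoints``).
    """
    if endpoints is None:
        host, ports = "127.0.0.1", (0, 0, 0)
    else:
        host, ports = endpoints[0], tuple(endpoints[1:4])
    return EnvBridge(env, host=host, ports=ports, cfg=cfg).start()


class _LineReader:
    def __init__(self, sock: socket.socket):
        self.sock = sock
        self.buf = b""

    def readline(self, timeout: float) -> bytes:
        deadline = time.monotonic() + timeout
        while b"\n" not in self.buf:
            remaining = deadline - time.monotonic()
            if remaining <= 0:
                raise TimeoutError("bridge read timed out")
            self.sock.settimeout(remaining)
            try:
                chunk = self.sock.recv(4096)
            except socket.timeout:
                continue
            if not chunk:
                raise ConnectionError("bridge closed the connection")
            self.buf += chunk
        line, self.buf = self.buf.split(b"\n", 1)
        return line


class RemoteEnv:
    """Client-side reset/step protocol over a bridge in lockstep mode."""

    def __init__(self, endpoints: dict, timeout: float = 10.0):
        self.timeout = timeout
        self._seq = 0.0
        self._socks = {}
        for kind in ("action", "observation", "reward"):
            s = socket.create_connection(tuple(endpoints[kind]), timeout=timeout)
            self._socks[kind] = s
        self._obs_reader = _LineReader(self._socks["observation"])
        self._reward_reader = _LineReader(self._socks["reward"])

    def _send(self, payload: dict) -> None:
        self._socks["action"].sendall(json.dumps(payload).encode() + b"\n")

    def _recv_stamped(self, reader: _LineReader) -> EnvMessage:
        deadline = time.monotonic() + self.timeout
        while True:
            msg = decode_message(reader.readline(max(deadline - time.monotonic(),
                                                     1e-3)))
            if msg.timestamp == self._seq:
                return msg

    def reset(self) -> Observation:
        self._seq += 1.0
        self._send({"kind": "reset", "timestamp": self._seq})
        obs = self._recv_stamped(self._obs_reader)
        self._recv_stamped(self._reward_reader)
        return _obs_from_message(obs)

    def step(self, action: int) -> StepResult:
        self._seq += 1.0
        self._send(json.loads(encode_message(
            EnvMessage("action", int(action), 1, self._seq)).decode()))
        obs = self._recv_stamped(self._obs_reader)
        rew = self._recv_stamped(self._reward_reader)
        return StepResult(_obs_from_message(obs), rew.scalar(), rew.done)

    def close(self) -> None:
        for s in self._socks.values():
            try:
                s.close()
            except OSError:
                pass
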