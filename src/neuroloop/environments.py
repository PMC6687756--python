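"""Self-contained benchmark environments with a reset/step protocol.

Both tasks follow the de-facto RL-toolkit convention: ``reset()``
returns the initial observation and ``step(action)`` returns a
:class:`StepResult` of (observation, reward, done).  Any third-party
environment exposing the same protocol can be driven by the closed loop
in its place.

MountainCar: an under-powered car in a valley must swing back and forth
to gain enough momentum to reach the right hilltop.  The classic
kinematics are pinned here:

    v <- clip(v + 0.001 * (a - 1) - 0.0025 * cos(3 x), +-0.07)
    x <- clip(x + v, [-1.2, 0.6]),  v <- 0 at the left wall

with actions a in {0: accelerate left, 1: no acceleration, 2: accelerate
right}, goal at x >= 0.5, and start drawn uniformly from [-0.6, -0.4] at
rest.  Reward shaping: a small punishment every step plus a goal bonus,
so that an architecture with a minimal-weight floor can learn a value
function despite the otherwise purely negative reinforcement.

FrozenLake: the standard non-slippery 4x4 grid (SFFF / FHFH / FFFH /
HFFG).  Actions move the agent one tile west/north/east/south; moves off
the grid leave the position unchanged.  Entering a hole incurs a
punishment and teleports the agent back to the start WITHOUT ending the
episode; entering the goal yields reward +1 and terminates.  Every step
additionally incurs a small punishment to encourage exploration.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .coding import Observation

__all__ = [
    "StepResult",
    "MountainCarState",
    "MountainCar",
    "GridWorld",
    "FrozenLake",
    "FROZENLAKE_MAP",
    "shortest_path_length",
]


@dataclass
class StepResult:
    observation: Observation
    reward: float
    done: bool


# ---------------------------------------------------------------------------
# MountainCar
# ---------------------------------------------------------------------------

@dataclass
class MountainCarState:
    x: float
    x_dot: float


class MountainCar:
    """Under-powered car on a hill, continuous state, 3 discrete actions."""

    n_actions = 3
    x_min, x_max = -1.2, 0.6
    v_max = 0.07
    force = 0.001
    gravity = 0.0025
    goal_x = 0.5

    def __init__(self, step_punishment: float = -0.01, goal_bonus: float = 1.0,
                 seed: int | None = None):
        self.step_punishment = float(step_punishment)
        self.goal_bonus = float(goal_bonus)
        self._rng = np.random.default_rng(seed)
        self.state = MountainCarState(-0.5, 0.0)
        self.cumulative_reward = 0.0

    @property
    def observation_bounds(self):
        """Documented state box, used to lay out place cells."""
        return [[self.x_min, self.x_max], [-self.v_max, self.v_max]]

    def _obs(self) -> Observation:
        return Observation(values=np.array([self.state.x, self.state.x_dot]))

    def reset(self) -> Observation:
        self.state = MountainCarState(float(self._rng.uniform(-0.6, -0.4)), 0.0)
        return self._obs()

    def step(self, action: int) -> StepResult:
        if action not in (0, 1, 2):
            raise ValueError(f"invalid action {action!r}")
        s = self.state
        v = s.x_dot + (action - 1) * self.force - np.cos(3 * s.x) * self.gravity
        v = float(np.clip(v, -self.v_max, self.v_max))
        x = float(np.clip(s.x + v, self.x_min, self.x_max))
        if x <= self.x_min and v < 0:
            v = 0.0
        self.state = MountainCarState(x, v)
        done = x >= self.goal_x
        reward = self.step_punishment + (self.goal_bonus if done else 0.0)
        self.cumulative_reward += reward
        return StepResult(self._obs(), reward, done)


# ---------------------------------------------------------------------------
# FrozenLake
# ---------------------------------------------------------------------------

FROZENLAKE_MAP = ("SFFF", "FHFH", "FFFH", "HFFG")

# actions: 0 west, 1 north, 2 east, 3 south (row-major states, 0 = top-left)
_MOVES = {0: (0, -1), 1: (-1, 0), 2: (0, 1), 3: (1, 0)}


@dataclass
class GridWorld:
    """4x4 tile map over {S, F, H, G} plus the agent position."""

    tiles: tuple = FROZENLAKE_MAP
    agent_pos: int = 0
    slippery: bool = False

    def __post_init__(self) -> None:
        flat = "".join(self.tiles)
        if flat.count("S") != 1 or flat.count("G") != 1:
            raise ValueError("map must contain exactly one S and one G")
        if flat[self.agent_pos] == "H":
            raise ValueError("agent cannot rest on a hole")
        if self.slippery:
            raise NotImplementedError("slippery transitions are out of scope")

    @property
    def n_rows(self) -> int:
        return len(self.tiles)

    @property
    def n_cols(self) -> int:
        return len(self.tiles[0])

    @property
    def n_states(self) -> int:
        return self.n_rows * self.n_cols

    def tile(self, state: int) -> str:
        return self.tiles[state // self.n_cols][state % self.n_cols]

    @property
    def start_state(self) -> int:
        return "".join(self.tiles).index("S")

    @property
    def goal_state(self) -> int:
        return "".join(self.tiles).index("G")

    def neighbor(self, state: int, action: int) -> int:
        """Target state of a move; off-grid moves return ``state``."""
        if action not in _MOVES:
            raise ValueError(f"invalid action {action!r}")
        dr, dc = _MOVES[action]
        r, c = divmod(state, self.n_cols)
        r2, c2 = r + dr, c + dc
        if not (0 <= r2 < self.n_rows and 0 <= c2 < self.n_cols):
            return state
        return r2 * self.n_cols + c2


class FrozenLake:
    """Non-slippery grid world with hole-reset and reward shaping."""

    n_actions = 4

    def __init__(self, tiles=FROZENLAKE_MAP, step_punishment: float = -0.01,
                 hole_punishment: float = -0.2, goal_reward: float = 1.0):
        self.world = GridWorld(tuple(tiles))
        self.step_punishment = float(step_punishment)
        self.hole_punishment = float(hole_punishment)
        self.goal_reward = float(goal_reward)
        self.cumulative_reward = 0.0

    @property
    def n_states(self) -> int:
        return self.world.n_states

    def _obs(self) -> Observation:
        return Observation(discrete_index=self.world.agent_pos)

    def reset(self) -> Observation:
        self.world.agent_pos = self.world.start_state
        return self._obs()

    def step(self, action: int) -> StepResult:
        target = self.world.neighbor(self.world.agent_pos, action)
        tile = self.world.tile(target)
        reward = self.step_punishment
        done = False
        if tile == "H":
            # falling into a hole punishes and resets to start; the
            # episode's step accounting continues
            reward += self.hole_punishment
            self.world.agent_pos = self.world.start_state
        elif tile == "G":
            reward += self.goal_reward
            self.world.agent_pos = target
            done = True
        else:
            self.world.agent_pos = target
        self.cumulative_reward += reward
        return StepResult(self._obs(), reward, done)

    def theoretical_optimum_per_step(self) -> float:
        """Best achievable long-run reward per step under the shaping."""
        n = shortest_path_length(self.world)
        return (self.goal_reward + n * self.step_punishment) / n


def shortest_path_length(world: GridWorld) -> int:
    """Breadth-first-search distance in moves from S to G over non-hole tiles."""
    start, goal = world.start_state, world.goal_state
    dist = {start: 0}
    queue = deque([start])
    while queue:
        s = queue.popleft()
        if s == goal:
            return dist[s]
        for a in range(4):
            t = world.neighbor(s, a)
            if t not in dist and world.tile(t) != "H":
                dist[t] = dist[s] + 1
                queue.append(t)
    raise ValueError("goal unreachable from start")
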