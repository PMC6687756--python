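"""Adapters between environment variables and neural activity.

Observation -> activity: Gaussian place-cell tuning over continuous
observation spaces (``encode``) and one-hot encoding for discrete state
spaces (``encode_discrete``).  Activity -> action: winner readout
(``argmax_decode``), binarization (``threshold_decode``) and linear
combination (``linear_decode``).  Adapters are composable: an adapter
chain such as discretize -> network -> argmax is declared in the
experiment configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
import itertools

import numpy as np

from .network import heaviside

__all__ = [
    "PlaceCellLayout",
    "DiscreteEncoderSpec",
    "Observation",
    "make_grid_layout",
    "encode",
    "encode_discrete",
    "argmax_decode",
    "threshold_decode",
    "linear_decode",
]

TIE_RULES = ("lowest_index", "random")


@dataclass
class Observation:
    """A single environment observation.

    Exactly one of ``values`` (continuous vector, environment units) or
    ``discrete_index`` (integer state id) drives the encoding, depending
    on the environment type.
    """

    values: np.ndarray | None = None
    discrete_index: int | None = None

    def __post_init__(self) -> None:
        if (self.values is None) == (self.discrete_index is None):
            raise ValueError(
                "exactly one of values / discrete_index must be set"
            )
        if self.values is not None:
            self.values = np.atleast_1d(np.asarray(self.values, dtype=float))


@dataclass
class PlaceCellLayout:
    """Gaussian tuning-curve centers and widths of a place-cell layer.

    centers : (n_cells, n_dims) preferred observations
    widths : per-dimension tuning widths (> 0)
    peak : response amplitude at the center
    """

    centers: np.ndarray
    widths: np.ndarray
    peak: float = 1.0

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.widths = np.atleast_1d(np.asarray(self.widths, dtype=float))
        if self.centers.shape[0] < 1:
            raise ValueError("need at least one place cell")
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("centers must be finite")
        if np.any(self.widths <= 0):
            raise ValueError("widths must be > 0")
        if self.widths.shape[0] != self.centers.shape[1]:
            raise ValueError("one width per observation dimension required")

    @property
    def n_cells(self) -> int:
        return self.centers.shape[0]

    @property
    def n_dims(self) -> int:
        return self.centers.shape[1]


@dataclass
class DiscreteEncoderSpec:
    """One-hot encoder for discrete state spaces (non-overlapping tuning)."""

    n_states: int
    peak: float = 1.0

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValueError("need at least one state")
        if self.peak <= 0:
            raise ValueError("peak must be > 0")


def make_grid_layout(bounds, n_per_dim, width_scale: float = 1.0) -> PlaceCellLayout:
    """Distribute place cells evenly on a grid spanning ``bounds``.

    ``bounds`` is a sequence of per-dimension ``[low, high]`` pairs and
    ``n_per_dim`` the number of cells along each dimension (an int is
    broadcast to all dimensions).  Centers form the Cartesian product of
    evenly spaced per-dimension grids including the endpoints; tuning
    widths are ``width_scale`` times the grid spacing per dimension.
    """
    bounds = np.atleast_2d(np.asarray(bounds, dtype=float))
    ndim = bounds.shape[0]
    if np.isscalar(n_per_dim):
        n_per_dim = [int(n_per_dim)] * ndim
    n_per_dim = [int(n) for n in n_per_dim]
    if len(n_per_dim) != ndim:
        raise ValueError("n_per_dim must match the number of dimensions")
    axes, widths = [], []
    for (low, high), n in zip(bounds, n_per_dim):
        if not (low < high):
            raise ValueError(f"degenerate bounds [{low}, {high}]")
        if n < 1:
            raise ValueError("n_per_dim entries must be >= 1")
        if n == 1:
            axes.append(np.array([(low + high) / 2.0]))
            spacing = high - low
        else:
            axes.append(np.linspace(low, high, n))
            spacing = (high - low) / (n - 1)
        widths.append(width_scale * spacing)
    centers = np.array(list(itertools.product(*axes)))
    return PlaceCellLayout(centers=centers, widths=np.array(widths))


def encode(obs: Observation, layout: PlaceCellLayout) -> np.ndarray:
    """Gaussian place-cell response to a continuous observation.

    ``activity_k = peak * exp(-sum_d (obs_d - center_kd)^2 / (2 width_d^2))``.
    Observations outside the layout bounds are encoded without clipping
    (Gaussian tails).
    """
    if obs.values is None:
        raise ValueError("encode requires a continuous observation")
    v = obs.values
    if v.shape[0] != layout.n_dims:
        raise ValueError(
            f"observation has {v.shape[0]} dims, layout expects {layout.n_dims}"
        )
    d2 = ((v[None, :] - layout.centers) / layout.widths[None, :]) ** 2
    return layout.peak * np.exp(-0.5 * d2.sum(axis=1))


def encode_discrete(index: int, n_states: int, peak: float = 1.0) -> np.ndarray:
    """One-hot encoding of a discrete state id, scaled by ``peak``.

    Discrete place cells do not overlap: exactly one cell responds.
    """
    index = int(index)
    if not (0 <= index < n_states):
        raise ValueError(f"state index {index} out of range [0, {n_states})")
    out = np.zeros(n_states)
    out[index] = peak
    return out


def argmax_decode(activities, tie_rule: str = "lowest_index",
                  rng: np.random.Generator | None = None) -> int:
    """Index of the most active unit; ties broken per ``tie_rule``."""
    a = np.asarray(activities, dtype=float)
    if a.size == 0:
        raise ValueError("argmax_decode: empty input")
    if tie_rule not in TIE_RULES:
        raise ValueError(f"unknown tie rule: {tie_rule!r}")
    best = np.flatnonzero(a == a.max())
    if tie_rule == "lowest_index" or best.size == 1:
        return int(best[0])
    if rng is None:
        raise ValueError("tie_rule='random' requires an rng")
    return int(rng.choice(best))


def threshold_decode(activities, thr: float) -> np.ndarray:
    """Binarize activities with the strict Heaviside: 1 iff activity > thr."""
    return heaviside(np.asarray(activities, dtype=float) - thr)


def linear_decode(D, activities) -> np.ndarray:
    """Linear readout ``D @ activities``."""
    D = np.atleast_2d(np.asarray(D, dtype=float))
    a = np.asarray(activities, dtype=float)
    if D.shape[1] != a.shape[0]:
        raise ValueError("decoder and activity dimensions do not conform")
    return D @ a
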