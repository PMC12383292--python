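"""Empirical trajectory diagnostics.

Turns simulated trajectories into the quantities the theory speaks
about: tail density bands (uniform persistence), first sustained drop
below a small threshold (extinction), and pathwise divergence between
two runs driven by common noise (global attractivity).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .integrate import Trajectory

__all__ = [
    "TailSummary",
    "PairDivergence",
    "tail_extrema",
    "extinction_time",
    "pair_divergence",
]


@dataclass(frozen=True)
class TailSummary:
    """Per-species extrema and mean over the last ``fraction`` of the run."""

    fraction: float
    t_start: float
    minima: np.ndarray
    maxima: np.ndarray
    means: np.ndarray


@dataclass(frozen=True)
class PairDivergence:
    """Tail sup-norm distance between two common-noise runs.

    ``ratio`` is the tail sup divided by the initial separation; under
    global attractivity it falls well below 1, under non-convergence it
    stays of order 1 for at least one species.
    """

    fraction: float
    tail_sup: np.ndarray
    initial_diff: np.ndarray
    ratio: np.ndarray


def tail_extrema(traj: Trajectory, fraction: float = 0.25) -> TailSummary:
    """Min/max/mean of each species over times ``>= (1 - fraction) * T``."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    t_start = (1.0 - fraction) * traj.horizon
    mask = traj.times >= t_start
    if not np.any(mask):
        raise ValueError("empty tail window")
    tail = traj.states[:, mask]
    return TailSummary(
        fraction=fraction,
        t_start=t_start,
        minima=tail.min(axis=1),
        maxima=tail.max(axis=1),
        means=tail.mean(axis=1),
    )


def extinction_time(
    traj: Trajectory,
    species: int,
    threshold: float = 1e-3,
    dwell: float = 10.0,
) -> Optional[float]:
    """Earliest ``t*`` with ``x_i(t) < threshold`` on all of ``[t*, t* + dwell]``.

    Returns None when no such window exists within the horizon; a window
    extending past the end of the run does not count.  Larger thresholds
    detect extinction earlier or at the same time.
    """
    if threshold <= 0.0:
        raise ValueError("threshold must be positive")
    if dwell < 0.0:
        raise ValueError("dwell must be non-negative")
    x = traj.species(species)
    below = x < threshold
    w = int(round(dwell / traj.dt))
    need = w + 1
    if need > below.size:
        return None
    # sliding-window count of samples below threshold
    cs = np.concatenate(([0], np.cumsum(below)))
    window_counts = cs[need:] - cs[:-need]
    hits = np.nonzero(window_counts == need)[0]
    if hits.size == 0:
        return None
    return float(traj.times[hits[0]])


def pair_divergence(
    traj_a: Trajectory, traj_b: Trajectory, fraction: float = 0.25
) -> PairDivergence:
    """Per-species tail sup |x_i - y_i| for two runs on one Brownian path."""
    if traj_a.times.shape != traj_b.times.shape or not np.allclose(
        traj_a.times, traj_b.times
    ):
        raise ValueError("trajectories are on different time grids")
    if traj_a.seed != traj_b.seed:
        raise ValueError(
            "trajectories were not driven by the same Brownian path "
            "(pathwise comparison is only meaningful per realization)"
        )
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    mask = traj_a.times >= (1.0 - fraction) * traj_a.horizon
    diff = np.abs(traj_a.states - traj_b.states)
    tail_sup = diff[:, mask].max(axis=1)
    initial = np.abs(traj_a.states[:, 0] - traj_b.states[:, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            initial > 0.0,
            tail_sup / np.where(initial > 0.0, initial, 1.0),
            np.where(tail_sup > 0.0, np.inf, 0.0),
        )
    return PairDivergence(
        fraction=fraction, tail_sup=tail_sup, initial_diff=initial, ratio=ratio
    )
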