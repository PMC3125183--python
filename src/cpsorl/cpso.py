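"""Complementary-particle escape from stagnated swarms (opposition-based restart).

When the swarm's global best has not improved for ``patience`` consecutive
iterations (default 5), half of the particles — chosen uniformly at random,
never the one holding gbest — are reflected through the midpoint of the
solution space:

    x_complement = X_max + X_min - x_selected      (per dimension)

Reflected particles get zero velocity but keep their personal bests, and
remain attracted by the unchanged gbest, so the swarm searches the opposite
region of the window without forgetting what it already found. The map is
an involution and keeps in-bounds positions in bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .pso import ComplementHook, Swarm

logger = logging.getLogger(__name__)


@dataclass
class StagnationState:
    """Counts consecutive iterations with an unchanged gbest fitness."""

    patience: int = 5
    replace_fraction: float = 0.5
    counter: int = 0
    last_gbest_fit: float = float("-inf")

    def __post_init__(self) -> None:
        if self.patience < 1 or not 0.0 < self.replace_fraction < 1.0:
            raise ValueError(f"invalid stagnation settings {self}")


def detect_stagnation(state: StagnationState, gbest_fit_prev: float, gbest_fit_now: float) -> bool:
    """Update the counter; True (and reset) once it reaches ``patience``.

    "Unchanged" is exact equality of the fitness value: fitness is computed
    on rounded-bp intervals, so an unmoved optimum reproduces it bit for bit.
    """
    if gbest_fit_now == gbest_fit_prev:
        state.counter += 1
    else:
        state.counter = 0
    if state.counter >= state.patience:
        state.counter = 0
        return True
    return False


def complement_positions(x: np.ndarray, xmin: np.ndarray, xmax: np.ndarray) -> np.ndarray:
    """Midpoint reflection X_max + X_min - x, componentwise."""
    return xmax + xmin - x


def complement_particles(swarm: Swarm, rng: np.random.Generator,
                         replace_fraction: float = 0.5) -> None:
    """Reflect a random half of the swarm (gbest holder excluded) in place."""
    n = swarm.size
    if n < 2:
        logger.info("swarm too small to complement (%d particles); skipped", n)
        return
    n_replace = int(np.floor(replace_fraction * n))
    if n_replace < 1:
        return
    eligible = np.array([i for i in range(n) if i != swarm.gbest_idx])
    chosen = rng.choice(eligible, size=min(n_replace, eligible.size), replace=False)
    swarm.x[chosen] = complement_positions(swarm.x[chosen], swarm.xmin, swarm.xmax)
    # keep reflected candidates inside the window (Fs bound depends on Fl)
    wlen = float(swarm.window.length)
    swarm.x[chosen, 0] = np.clip(swarm.x[chosen, 0], 0.0, wlen - swarm.x[chosen, 1])
    swarm.v[chosen] = 0.0
    # pbest and gbest intentionally retained


def make_complement_hook(patience: int = 5, replace_fraction: float = 0.5) -> ComplementHook:
    """A fresh per-run hook wiring stagnation detection to the complement step."""
    state = StagnationState(patience=patience, replace_fraction=replace_fraction)

    def hook(swarm: Swarm, rng: np.random.Generator) -> None:
        prev = state.last_gbest_fit
        now = swarm.gbest_fit
        state.last_gbest_fit = now
        if prev == float("-inf"):
            return  # first observation; nothing to compare yet
        if detect_stagnation(state, prev, now):
            complement_particles(swarm, rng, replace_fraction)
            swarm.gbest_unchanged = 0
        elif now == prev:
            swarm.gbest_unchanged += 1
        else:
            swarm.gbest_unchanged = 0

    return hook
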