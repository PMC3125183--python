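"""Particle swarm search for the best island inside one window.

Each particle encodes a candidate island as (Fs, Fl): the start offset
within the window and the length in bp; the end Fe = Fs + Fl is derived.
Standard PSO dynamics with a linearly annealed inertia weight:

    v_new = w * v + c1*r1*(pbest - x) + c2*r2*(gbest - x)
    x_new = x + v_new
    w(i)  = w_max - (w_max - w_min) * i / i_max

Positions are real-valued during flight and rounded to integer bp only at
fitness evaluation; out-of-bounds moves are repaired by clamping (length
first, then start so the candidate stays inside the window). Velocities
are clipped to ±v_max per dimension (default window_size / 5) since
unbounded velocities diverge on bp-scale coordinates.

The whole swarm is stored as numpy arrays, one row per particle, so an
iteration is a handful of vectorized operations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .fitness import FitnessConfig, fitness_batch
from .refine import CpGIsland, island_from_interval
from .sequence import (
    GenomeSequence,
    Interval,
    SequenceProfile,
    mask_intervals,
    meets_criteria,
    count_nucleotides,
)

logger = logging.getLogger(__name__)

DEFAULT_RESTARTS_PER_WINDOW = 5


@dataclass(frozen=True)
class SwarmConfig:
    """Swarm hyperparameters (defaults are the method's published settings)."""

    population: int = 300
    iterations: int = 100
    c1: float = 2.0
    c2: float = 2.0
    w_max: float = 0.9
    w_min: float = 0.4
    v_max: Optional[float] = None  # None -> window length / 5
    seed: int = 1

    def __post_init__(self) -> None:
        if self.population < 2 or self.iterations < 1:
            raise ValueError("population must be > 1 and iterations >= 1")
        if self.w_min > self.w_max:
            raise ValueError("w_min must not exceed w_max")
        if self.v_max is not None and self.v_max <= 0:
            raise ValueError("v_max must be positive")


@dataclass
class Swarm:
    """Vectorized swarm state. Row i of each array belongs to particle i.

    x columns are (Fs, Fl) in window-local bp. ``xmin``/``xmax`` are the
    per-dimension solution-space bounds used for clamping and for the
    complementary reflection.
    """

    x: np.ndarray
    v: np.ndarray
    fit: np.ndarray
    pbest_x: np.ndarray
    pbest_fit: np.ndarray
    gbest_x: np.ndarray = field(default=None)  # type: ignore[assignment]
    gbest_fit: float = -np.inf
    gbest_idx: int = -1
    gbest_unchanged: int = 0
    xmin: np.ndarray = field(default=None)  # type: ignore[assignment]
    xmax: np.ndarray = field(default=None)  # type: ignore[assignment]
    window: Interval = field(default=None)  # type: ignore[assignment]
    v_max: float = 0.0

    @property
    def size(self) -> int:
        return self.x.shape[0]


def inertia_weight(move_i: int, move_max: int, cfg: SwarmConfig) -> float:
    """Linear anneal from w_max at iteration 0 to w_min at the last iteration."""
    if move_max <= 0:
        raise ValueError("move_max must be positive")
    if not 0 <= move_i <= move_max:
        raise ValueError(f"move_i {move_i} outside [0, {move_max}]")
    return cfg.w_max - (cfg.w_max - cfg.w_min) * move_i / move_max


def window_bounds(window_length: int, fit_cfg: FitnessConfig) -> tuple[np.ndarray, np.ndarray]:
    """(X_min, X_max) per dimension: Fs in [0, L-len_lo], Fl in [len_lo, min(len_hi, L)]."""
    fl_hi = min(fit_cfg.len_hi, window_length)
    xmin = np.array([0.0, float(fit_cfg.len_lo)])
    xmax = np.array([float(window_length - fit_cfg.len_lo), float(fl_hi)])
    return xmin, xmax


def candidate_intervals(swarm: Swarm, fit_cfg: FitnessConfig) -> tuple[np.ndarray, np.ndarray]:
    """Round particle positions to integer bp intervals, repaired into the window."""
    wlen = swarm.window.length
    fl = np.rint(swarm.x[:, 1]).astype(np.int64)
    fl = np.clip(fl, fit_cfg.len_lo, min(fit_cfg.len_hi, wlen))
    fs = np.rint(swarm.x[:, 0]).astype(np.int64)
    fs = np.clip(fs, 0, wlen - fl)
    starts = swarm.window.start + fs
    return starts, starts + fl


def evaluate_swarm(swarm: Swarm, profile: SequenceProfile, fit_cfg: FitnessConfig) -> None:
    """Recompute every particle's fitness and refresh pbest/gbest."""
    starts, ends = candidate_intervals(swarm, fit_cfg)
    swarm.fit = fitness_batch(profile, starts, ends, fit_cfg)
    improved = swarm.fit > swarm.pbest_fit
    swarm.pbest_fit = np.where(improved, swarm.fit, swarm.pbest_fit)
    swarm.pbest_x = np.where(improved[:, None], swarm.x, swarm.pbest_x)
    best = int(np.argmax(swarm.pbest_fit))
    if swarm.pbest_fit[best] > swarm.gbest_fit:
        swarm.gbest_fit = float(swarm.pbest_fit[best])
        swarm.gbest_x = swarm.pbest_x[best].copy()
        swarm.gbest_idx = best


def initialize_swarm(
    window: Interval,
    cfg: SwarmConfig,
    fit_cfg: FitnessConfig,
    profile: SequenceProfile,
    rng: np.random.Generator,
) -> Optional[Swarm]:
    """Uniform random positions within bounds, zero velocity, pbest = x."""
    wlen = window.length
    if wlen < fit_cfg.len_lo:
        logger.info(
            "window [%d,%d) shorter than minimum island length %d bp; skipped",
            window.start, window.end, fit_cfg.len_lo,
        )
        return None
    xmin, xmax = window_bounds(wlen, fit_cfg)
    n = cfg.population
    x = rng.uniform(xmin, xmax, size=(n, 2))
    # repair so every initial candidate fits in the window
    x[:, 0] = np.minimum(x[:, 0], wlen - x[:, 1])
    v = np.zeros_like(x)
    v_max = cfg.v_max if cfg.v_max is not None else wlen / 5.0
    swarm = Swarm(
        x=x, v=v,
        fit=np.full(n, -np.inf),
        pbest_x=x.copy(),
        pbest_fit=np.full(n, -np.inf),
        xmin=xmin, xmax=xmax,
        window=window, v_max=v_max,
    )
    evaluate_swarm(swarm, profile, fit_cfg)
    return swarm


def update_velocity(swarm: Swarm, w: float, cfg: SwarmConfig, rng: np.random.Generator) -> None:
    """PSO velocity update; r1, r2 drawn fresh per particle, clip to ±v_max."""
    n = swarm.size
    r1 = rng.uniform(0.0, 1.0, size=(n, 1))
    r2 = rng.uniform(0.0, 1.0, size=(n, 1))
    swarm.v = (
        w * swarm.v
        + cfg.c1 * r1 * (swarm.pbest_x - swarm.x)
        + cfg.c2 * r2 * (swarm.gbest_x[None, :] - swarm.x)
    )
    np.clip(swarm.v, -swarm.v_max, swarm.v_max, out=swarm.v)


def update_position(swarm: Swarm) -> None:
    """x += v, then clamp: Fl into its band, Fs so the candidate stays inside."""
    swarm.x = swarm.x + swarm.v
    swarm.x[:, 1] = np.clip(swarm.x[:, 1], swarm.xmin[1], swarm.xmax[1])
    wlen = float(swarm.window.length)
    swarm.x[:, 0] = np.clip(swarm.x[:, 0], 0.0, wlen - swarm.x[:, 1])


ComplementHook = Callable[[Swarm, np.random.Generator], None]


def optimize_swarm(
    swarm: Swarm,
    profile: SequenceProfile,
    cfg: SwarmConfig,
    fit_cfg: FitnessConfig,
    rng: np.random.Generator,
    complement_hook: Optional[ComplementHook] = None,
    on_iteration: Optional[Callable[[int, Swarm], None]] = None,
) -> Swarm:
    """Run the iteration loop on an already initialized swarm."""
    for i in range(cfg.iterations):
        w = inertia_weight(i, cfg.iterations, cfg)
        update_velocity(swarm, w, cfg, rng)
        update_position(swarm)
        evaluate_swarm(swarm, profile, fit_cfg)
        if complement_hook is not None:
            complement_hook(swarm, rng)
        if on_iteration is not None:
            on_iteration(i, swarm)
    return swarm


def gbest_island(
    swarm: Swarm,
    seq: GenomeSequence,
    fit_cfg: FitnessConfig,
    offset: int = 0,
) -> Optional[CpGIsland]:
    """Materialize gbest as an island if it satisfies the criteria, else None."""
    single = Swarm(
        x=swarm.gbest_x[None, :], v=np.zeros((1, 2)),
        fit=np.zeros(1), pbest_x=swarm.gbest_x[None, :], pbest_fit=np.zeros(1),
        xmin=swarm.xmin, xmax=swarm.xmax, window=swarm.window, v_max=swarm.v_max,
    )
    starts, ends = candidate_intervals(single, fit_cfg)
    iv = Interval(int(starts[0]) + offset, int(ends[0]) + offset)
    counts = count_nucleotides(seq, iv)
    if not meets_criteria(iv, counts, fit_cfg.criteria):
        return None
    return island_from_interval(seq, iv, fit_cfg)


def run_window(
    seq: GenomeSequence,
    window: Interval,
    cfg: SwarmConfig,
    fit_cfg: FitnessConfig,
    rng: np.random.Generator,
    complement_hook: Optional[ComplementHook] = None,
    profile: Optional[SequenceProfile] = None,
) -> Optional[CpGIsland]:
    """One full swarm run in one window; returns the best feasible island."""
    if profile is None:
        profile = SequenceProfile(seq)
    swarm = initialize_swarm(window, cfg, fit_cfg, profile, rng)
    if swarm is None:
        return None
    optimize_swarm(swarm, profile, cfg, fit_cfg, rng, complement_hook)
    return gbest_island(swarm, seq, fit_cfg)


def _dedup_islands(
    islands: list[CpGIsland], seq: GenomeSequence, fit_cfg: FitnessConfig
) -> list[CpGIsland]:
    """Union islands found twice across overlapping windows.

    If a union of overlapping finds fails the criteria (possible when two
    windows report different fragments of distinct islands butted together),
    the higher-fitness constituent is kept instead.
    """
    if not islands:
        return []
    islands = sorted(islands, key=lambda i: (i.start, i.end))
    out = [islands[0]]
    for isl in islands[1:]:
        prev = out[-1]
        if isl.start < prev.end:  # overlap from window seams
            span = Interval(prev.start, max(prev.end, isl.end))
            counts = count_nucleotides(seq, span)
            if meets_criteria(span, counts, fit_cfg.criteria):
                out[-1] = island_from_interval(seq, span, fit_cfg)
            elif isl.fitness > prev.fitness:
                out[-1] = isl
        else:
            out.append(isl)
    return out


def extract_islands(
    seq: GenomeSequence,
    cfg: SwarmConfig,
    fit_cfg: FitnessConfig,
    windows: list[Interval],
    restarts_per_window: int = DEFAULT_RESTARTS_PER_WINDOW,
    rng: Optional[np.random.Generator] = None,
    complement_hook_factory: Optional[Callable[[], ComplementHook]] = None,
) -> list[CpGIsland]:
    """Find all islands: per window, run the swarm, mask the find, repeat.

    Deflation: after a feasible gbest is found its span is masked (set to N)
    in a working copy of the window so the next restart must find a different
    island; up to ``restarts_per_window`` islands per window. Islands pooled
    over windows are deduplicated (overlaps from window seams unioned) and
    their statistics recomputed on the untouched input sequence.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    found: list[CpGIsland] = []
    for window in windows:
        local = GenomeSequence(
            name=seq.name, residues=seq.residues[window.start : window.end]
        )
        local_window = Interval(0, window.length)
        for _ in range(restarts_per_window):
            hook = complement_hook_factory() if complement_hook_factory else None
            island = run_window(local, local_window, cfg, fit_cfg, rng, hook)
            if island is None:
                break
            found.append(
                island_from_interval(
                    seq,
                    Interval(island.start + window.start, island.end + window.start),
                    fit_cfg,
                )
            )
            local = mask_intervals(local, [island.interval])
    return _dedup_islands(found, seq, fit_cfg)
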