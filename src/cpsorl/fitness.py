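"""Scalar fitness of a candidate island.

A candidate is *feasible* when all three criteria components hold
(length, GC content, O/E ratio at or above their thresholds). Feasible
candidates score

    fitness = GC + O/E + length_score,     length_score in [0, 1]

so higher GC, higher O/E and greater length are all rewarded. Infeasible
candidates score ``0.1 * (number of satisfied components)``, which keeps a
gradient toward feasibility while guaranteeing strict dominance: the
infeasible range [0, 0.2] never reaches the feasible minimum
0.5 + 0.6 + 0 = 1.1 under GGF thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence import (
    GGF,
    CriteriaSet,
    NucleotideCounts,
    SequenceProfile,
    gc_content,
    oe_ratio,
)

PENALTY_SCALE = 0.1


@dataclass(frozen=True)
class FitnessConfig:
    """Criteria plus the island length band used for score normalization.

    ``len_lo``/``len_hi`` default to the canonical 200-2000 bp island length
    range; the length component of the fitness is the position within this
    band, clipped to [0, 1].
    """

    criteria: CriteriaSet = field(default_factory=lambda: GGF)
    len_lo: int = 200
    len_hi: int = 2000

    def __post_init__(self) -> None:
        if not 0 < self.len_lo < self.len_hi:
            raise ValueError(f"need 0 < len_lo < len_hi, got {self.len_lo}, {self.len_hi}")


def length_score(length: float, cfg: FitnessConfig) -> float:
    """Linear normalization of length to [0, 1] over [len_lo, len_hi]."""
    return float(np.clip((length - cfg.len_lo) / (cfg.len_hi - cfg.len_lo), 0.0, 1.0))


def particle_fitness(c: NucleotideCounts, length: int, cfg: FitnessConfig) -> float:
    """Fitness of one candidate interval from its counts and length."""
    if c.N == 0:
        return 0.0
    gc = gc_content(c)
    oe = oe_ratio(c)
    crit = cfg.criteria
    ok = (length >= crit.min_length, gc >= crit.min_gc, oe >= crit.min_oe)
    if all(ok):
        return gc + oe + length_score(length, cfg)
    return PENALTY_SCALE * sum(ok)


def fitness_batch(
    profile: SequenceProfile,
    starts: np.ndarray,
    ends: np.ndarray,
    cfg: FitnessConfig,
) -> np.ndarray:
    """Vectorized :func:`particle_fitness` over arrays of intervals.

    Identical arithmetic to the scalar path; used by the swarm inner loop
    where a fitness value is needed for every particle every iteration.
    """
    n_c, n_g, n_valid, n_cpg = profile.counts_batch(starts, ends)
    length = np.asarray(ends, dtype=np.int64) - np.asarray(starts, dtype=np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(n_valid > 0, (n_c + n_g) / np.maximum(n_valid, 1), 0.0)
        denom = n_c * n_g
        oe = np.where(denom > 0, n_cpg * n_valid / np.maximum(denom, 1), 0.0)
    crit = cfg.criteria
    ok_len = length >= crit.min_length
    ok_gc = gc >= crit.min_gc
    ok_oe = oe >= crit.min_oe
    feasible = ok_len & ok_gc & ok_oe
    lscore = np.clip((length - cfg.len_lo) / (cfg.len_hi - cfg.len_lo), 0.0, 1.0)
    n_ok = ok_len.astype(np.int64) + ok_gc.astype(np.int64) + ok_oe.astype(np.int64)
    fit = np.where(feasible, gc + oe + lscore, PENALTY_SCALE * n_ok)
    return np.where(n_valid > 0, fit, 0.0)
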