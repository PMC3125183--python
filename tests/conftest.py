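"""Shared fixtures and independent oracle helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from cpsorl import (
    FitnessConfig,
    GenomeSequence,
    Interval,
    IslandSpec,
    SwarmConfig,
    generate_background,
    island_from_interval,
    make_complement_hook,
    plant_islands,
)
from cpsorl.pso import evaluate_swarm, initialize_swarm, optimize_swarm
from cpsorl.sequence import SequenceProfile


def seq_of(residues: str, name: str = "t") -> GenomeSequence:
    return GenomeSequence(name=name, residues=residues)


def bitmap_confusion(predicted, reference, L):
    """Per-base bitmap oracle for confusion counts (independent of the
    interval-arithmetic implementation)."""
    pred = np.zeros(L, dtype=bool)
    ref = np.zeros(L, dtype=bool)
    for iv in predicted:
        pred[iv.start : iv.end] = True
    for iv in reference:
        ref[iv.start : iv.end] = True
    tp = int((pred & ref).sum())
    fp = int((pred & ~ref).sum())
    fn = int((~pred & ref).sum())
    tn = int((~pred & ~ref).sum())
    return tp, fp, tn, fn


@pytest.fixture(scope="session")
def ggf_fit_cfg() -> FitnessConfig:
    return FitnessConfig()


def make_two_bump(seed: int) -> GenomeSequence:
    """6 kb sequence with a modest island near the left end and a clearly
    better one in the right half; used for the stagnation-escape checks."""
    rng = np.random.default_rng(seed)
    bg = generate_background(6000, 0.40, 0.2, rng)
    seq, _ = plant_islands(
        bg,
        [
            IslandSpec(400, 0.55, 0.70, position=500),
            IslandSpec(800, 0.65, 0.90, position=4800),
        ],
        min_gap=300,
        rng=rng,
    )
    return seq


def run_two_bump(seed: int, use_cpso: bool) -> bool:
    """One escape trial: swarm seeded on the worse bump; success means the
    run reaches (95% of) the better island's fitness."""
    cfg = SwarmConfig()
    fit_cfg = FitnessConfig()
    seq = make_two_bump(seed)
    profile = SequenceProfile(seq)
    rng = np.random.default_rng(1000 + seed)
    swarm = initialize_swarm(Interval(0, seq.length), cfg, fit_cfg, profile, rng)
    n = swarm.size
    swarm.x[:, 0] = rng.uniform(400, 1000, n)
    swarm.x[:, 1] = rng.uniform(200, 500, n)
    swarm.x[:, 0] = np.minimum(swarm.x[:, 0], seq.length - swarm.x[:, 1])
    swarm.pbest_x = swarm.x.copy()
    swarm.pbest_fit = np.full(n, -np.inf)
    swarm.gbest_fit = -np.inf
    evaluate_swarm(swarm, profile, fit_cfg)
    hook = make_complement_hook() if use_cpso else None
    optimize_swarm(swarm, profile, cfg, fit_cfg, rng, hook)
    better = island_from_interval(seq, Interval(4800, 5600), fit_cfg)
    return bool(swarm.gbest_fit >= 0.95 * better.fitness)
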