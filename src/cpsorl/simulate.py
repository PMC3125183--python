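"""Synthetic benchmark sequences: CpG-depleted background with planted islands.

Vertebrate genomic background is modelled as a first-order Markov chain
over {A,C,G,T}: the base distribution fixes the GC level, and the C→G
transition probability is multiplied by a suppression factor (then the row
is renormalized), which depresses the CpG dinucleotide frequency the way
methylation-driven CpG decay does in real genomes — realized O/E tracks
the suppression factor. Islands are generated by the same chain with high
GC and little or no suppression, rejection-sampled until their empirical
GC and O/E land within ±0.03 of the targets, and spliced into the
background at non-overlapping positions; the splice coordinates are the
ground truth.

The module also provides the two reference searchers used as test oracles:
an exhaustive best-segment scan (the true optimum of the swarm's objective)
and a minimal fixed-window sliding scanner of the classical kind.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .fitness import FitnessConfig, fitness_batch
from .refine import CpGIsland, island_from_interval
from .sequence import (
    CriteriaSet,
    GenomeSequence,
    Interval,
    SequenceProfile,
    count_nucleotides,
    gc_content,
    oe_ratio,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")
_C, _G = 1, 2  # indices into BASES

EXHAUSTIVE_GUARD_BP = 5000


@dataclass(frozen=True)
class IslandSpec:
    """Blueprint of one planted island; must itself satisfy the GGF thresholds."""

    length: int
    target_gc: float
    target_oe: float
    position: Union[int, str] = "random"

    def __post_init__(self) -> None:
        if self.length < 200 or self.target_gc < 0.5 or self.target_oe < 0.6:
            raise ValueError(f"island spec must be GGF-feasible: {self}")


def _transition_matrix(gc: float, cpg_suppression: float) -> np.ndarray:
    """Row-stochastic 4x4 matrix with base mix ~gc and suppressed C→G."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    T = np.tile(p, (4, 1))
    T[_C, _G] *= cpg_suppression
    T[_C] /= T[_C].sum()
    return T


def _markov_indices(L: int, T: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample a length-L base-index path; inverse-CDF against one uniform draw per step."""
    cum = np.cumsum(T, axis=1)
    u = rng.random(L)
    out = np.empty(L, dtype=np.int8)
    p0 = np.cumsum(np.array([0.25, 0.25, 0.25, 0.25]))
    out[0] = np.searchsorted(p0, u[0], side="right")
    prev = out[0]
    for i in range(1, L):
        prev = int(np.searchsorted(cum[prev], u[i], side="right"))
        out[i] = prev
    return np.minimum(out, 3)


def _indices_to_sequence(name: str, idx: np.ndarray) -> GenomeSequence:
    return GenomeSequence(name=name, residues=BASES[idx].tobytes().decode())


def generate_background(
    L: int,
    gc: float = 0.41,
    cpg_suppression: float = 0.25,
    rng: Optional[np.random.Generator] = None,
    name: str = "synthetic",
) -> GenomeSequence:
    """CpG-depleted random background of length L.

    Defaults (GC 0.41, suppression 0.25) imitate bulk human genomic DNA:
    ~41% GC with the CpG dimer at roughly a quarter of its expected
    frequency.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    if rng is None:
        rng = np.random.default_rng()
    T = _transition_matrix(gc, cpg_suppression)
    return _indices_to_sequence(name, _markov_indices(L, T, rng))


def _suppression_for_target_oe(target_oe: float, gc: float) -> float:
    """Invert the chain's approximate O/E ≈ s / (1 - p_G (1 - s)) relation."""
    p_g = gc / 2
    s = target_oe * (1 - p_g) / (1 - target_oe * p_g)
    return float(np.clip(s, 0.01, 1.5))


def generate_island_segment(
    spec: IslandSpec,
    rng: np.random.Generator,
    tol: float = 0.03,
    max_tries: int = 500,
) -> str:
    """Rejection-sample a segment whose empirical GC and O/E hit the targets ±tol."""
    s = _suppression_for_target_oe(spec.target_oe, spec.target_gc)
    T = _transition_matrix(spec.target_gc, s)
    for _ in range(max_tries):
        seg = _indices_to_sequence("seg", _markov_indices(spec.length, T, rng))
        counts = count_nucleotides(seg, Interval(0, spec.length))
        if (
            abs(gc_content(counts) - spec.target_gc) <= tol
            and abs(oe_ratio(counts) - spec.target_oe) <= tol
        ):
            return seg.residues
    raise RuntimeError(f"could not realize island spec {spec} in {max_tries} tries")


def plant_islands(
    bg: GenomeSequence,
    specs: Sequence[IslandSpec],
    min_gap: int = 300,
    rng: Optional[np.random.Generator] = None,
) -> tuple[GenomeSequence, list[Interval]]:
    """Splice one segment per spec into the background; returns (sequence, truth).

    Placement keeps pairwise gaps (and gaps to the sequence ends) >= min_gap
    so planted islands can never be merged by the refinement step by accident.
    """
    if rng is None:
        rng = np.random.default_rng()
    placed: list[tuple[int, IslandSpec]] = []
    fixed = [(int(s.position), s) for s in specs if s.position != "random"]
    free = [s for s in specs if s.position == "random"]
    placed.extend(fixed)

    def conflicts(start: int, length: int) -> bool:
        for other_start, other in placed:
            if start < other_start + other.length + min_gap and other_start < start + length + min_gap:
                return True
        return False

    for spec in free:
        hi = bg.length - spec.length - min_gap
        if hi <= min_gap:
            raise ValueError(f"background too short to place {spec}")
        for _ in range(1000):
            start = int(rng.integers(min_gap, hi))
            if not conflicts(start, spec.length):
                placed.append((start, spec))
                break
        else:
            raise ValueError(f"could not place island spec {spec} with min_gap {min_gap}")
    for start, spec in placed:
        if start < 0 or start + spec.length > bg.length:
            raise ValueError(f"island spec {spec} at {start} outside the background")
    placed.sort()
    for (s1, sp1), (s2, sp2) in zip(placed, placed[1:]):
        if s2 - (s1 + sp1.length) < min_gap:
            raise ValueError("fixed island positions violate min_gap")

    residues = list(bg.residues)
    truth: list[Interval] = []
    for start, spec in placed:
        segment = generate_island_segment(spec, rng)
        residues[start : start + spec.length] = segment
        truth.append(Interval(start, start + spec.length))
    return GenomeSequence(name=bg.name, residues="".join(residues)), truth


def exhaustive_best_segment(
    seq: GenomeSequence,
    fit_cfg: FitnessConfig,
    guard_bp: int = EXHAUSTIVE_GUARD_BP,
) -> tuple[Interval, float]:
    """Global maximum of the particle fitness over every (start, length).

    O(L^2) reference oracle for the swarm; refuses sequences longer than
    ``guard_bp``. Ties break toward smaller start, then smaller length.
    """
    L = seq.length
    if L > guard_bp:
        raise ValueError(f"sequence length {L} exceeds oracle guard {guard_bp} bp")
    if L < fit_cfg.len_lo:
        raise ValueError(f"sequence shorter than minimum island length {fit_cfg.len_lo}")
    profile = SequenceProfile(seq)
    best_fit = -np.inf
    best_start = best_len = -1
    for length in range(fit_cfg.len_lo, min(fit_cfg.len_hi, L) + 1):
        starts = np.arange(0, L - length + 1, dtype=np.int64)
        fits = fitness_batch(profile, starts, starts + length, fit_cfg)
        i = int(np.argmax(fits))  # argmax takes the first = smallest start
        if fits[i] > best_fit or (fits[i] == best_fit and i < best_start):
            best_fit = float(fits[i])
            best_start, best_len = i, length
    return Interval(best_start, best_start + best_len), best_fit


def sliding_window_baseline(
    seq: GenomeSequence,
    crit: CriteriaSet,
    win: int = 200,
    step: int = 1,
) -> list[CpGIsland]:
    """Classical fixed-window scanner: mark every window meeting the criteria,
    merge overlapping marked windows, emit maximal runs as islands."""
    L = seq.length
    if L < win:
        return []
    profile = SequenceProfile(seq)
    starts = np.arange(0, L - win + 1, step, dtype=np.int64)
    n_c, n_g, n_valid, n_cpg = profile.counts_batch(starts, starts + win)
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(n_valid > 0, (n_c + n_g) / np.maximum(n_valid, 1), 0.0)
        oe = np.where(
            n_c * n_g > 0, n_cpg * n_valid / np.maximum(n_c * n_g, 1), 0.0
        )
    ok = (win >= crit.min_length) & (gc >= crit.min_gc) & (oe >= crit.min_oe)
    fit_cfg = FitnessConfig(criteria=crit)
    islands: list[CpGIsland] = []
    run_start = None
    prev_end = None
    for s, good in zip(starts, ok):
        if good:
            if run_start is None or s > prev_end:
                if run_start is not None:
                    islands.append(
                        island_from_interval(seq, Interval(run_start, prev_end), fit_cfg)
                    )
                run_start = int(s)
            prev_end = int(s) + win
    if run_start is not None:
        islands.append(island_from_interval(seq, Interval(run_start, prev_end), fit_cfg))
    return islands


#: Canonical regression fixture: parameter grids for the 8 planted islands.
FIXTURE_LENGTHS = (300, 500, 700, 900, 1100, 1300, 1500, 1800)
FIXTURE_GC = (0.55, 0.58, 0.60, 0.62, 0.65, 0.57, 0.63, 0.60)
FIXTURE_OE = (0.70, 0.75, 0.80, 0.85, 0.90, 0.72, 0.78, 0.88)


def standard_fixture(
    seed: int,
    L: int = 100_000,
    gc: float = 0.41,
    cpg_suppression: float = 0.25,
    n_islands: int = 8,
    min_gap: int = 1000,
) -> tuple[GenomeSequence, list[Interval]]:
    """The repo's canonical planted-island benchmark.

    100 kb CpG-depleted background (GC 0.41, suppression 0.25) with 8
    islands spanning lengths 300-1800 bp, GC 0.55-0.65 and O/E 0.70-0.90 at
    random non-adjacent positions. Only the seed varies between replicates.
    """
    rng = np.random.default_rng(seed)
    bg = generate_background(L, gc, cpg_suppression, rng, name=f"synthetic_seed{seed}")
    specs = [
        IslandSpec(
            length=FIXTURE_LENGTHS[i % len(FIXTURE_LENGTHS)],
            target_gc=FIXTURE_GC[i % len(FIXTURE_GC)],
            target_oe=FIXTURE_OE[i % len(FIXTURE_OE)],
        )
        for i in range(n_islands)
    ]
    return plant_islands(bg, specs, min_gap=min_gap, rng=rng)


def simulate_methylation(
    seq: GenomeSequence,
    truth: Sequence[Interval],
    rng: np.random.Generator,
    rate_inside: float = 0.30,
    rate_outside: float = 0.80,
) -> list[int]:
    """Methylation site positions drawn at CpG cytosines.

    Real islands are hypomethylated relative to bulk genome, hence the lower
    inside-island rate by default. Returns sorted 0-based positions.
    """
    arr = np.frombuffer(seq.residues.encode(), dtype="S1")
    cpg_pos = np.where((arr[:-1] == b"C") & (arr[1:] == b"G"))[0]
    inside = np.zeros(cpg_pos.shape, dtype=bool)
    for iv in truth:
        inside |= (cpg_pos >= iv.start) & (cpg_pos < iv.end)
    rates = np.where(inside, rate_inside, rate_outside)
    keep = rng.random(cpg_pos.shape) < rates
    return [int(p) for p in cpg_pos[keep]]
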