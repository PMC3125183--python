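"""Merge-based refinement of predicted islands ("reinforcement" step).

Predicted islands are often fragments of one true island. Scanning left to
right, any two adjacent islands closer than ``gap_threshold`` (default
200 bp) are tentatively combined into the single spanning interval, gap
included. The combination is *rewarded* (kept) only if the spanning
interval still satisfies the active criteria set; otherwise it is
*penalized* (rejected) and both islands stand. Passes repeat until a whole
pass changes nothing, so the result is a fixed point of the merge rule.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fitness import FitnessConfig, particle_fitness
from .sequence import (
    CriteriaSet,
    GenomeSequence,
    Interval,
    count_nucleotides,
    gc_content,
    meets_criteria,
    oe_ratio,
)

DEFAULT_GAP_THRESHOLD = 200


@dataclass(frozen=True)
class CpGIsland:
    """A predicted island with its composition statistics."""

    interval: Interval
    gc: float
    oe: float
    fitness: float

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def length(self) -> int:
        return self.interval.length


def island_from_interval(
    seq: GenomeSequence, iv: Interval, fit_cfg: FitnessConfig
) -> CpGIsland:
    """Build an island with statistics recomputed from the sequence."""
    c = count_nucleotides(seq, iv)
    if c.N == 0:
        return CpGIsland(interval=iv, gc=0.0, oe=0.0, fitness=0.0)
    return CpGIsland(
        interval=iv,
        gc=gc_content(c),
        oe=oe_ratio(c),
        fitness=particle_fitness(c, iv.length, fit_cfg),
    )


def _check_sorted_disjoint(islands: list[CpGIsland]) -> None:
    for prev, nxt in zip(islands, islands[1:]):
        if nxt.start < prev.end:
            raise ValueError(
                f"islands must be sorted and non-overlapping; "
                f"[{prev.start},{prev.end}) then [{nxt.start},{nxt.end})"
            )


def merge_pass(
    islands: list[CpGIsland],
    seq: GenomeSequence,
    gap_threshold: int,
    crit: CriteriaSet,
    fit_cfg: FitnessConfig | None = None,
) -> list[CpGIsland]:
    """One left-to-right merge scan; accepted merges chain immediately."""
    _check_sorted_disjoint(islands)
    if fit_cfg is None:
        fit_cfg = FitnessConfig(criteria=crit)
    out: list[CpGIsland] = []
    for isl in islands:
        if out:
            prev = out[-1]
            gap = isl.start - prev.end
            if gap < gap_threshold:
                span = Interval(prev.start, isl.end)
                counts = count_nucleotides(seq, span)
                if meets_criteria(span, counts, crit):
                    out[-1] = island_from_interval(seq, span, fit_cfg)
                    continue  # reward: merged island may merge again
        out.append(isl)
    return out


def refine(
    islands: list[CpGIsland],
    seq: GenomeSequence,
    gap_threshold: int = DEFAULT_GAP_THRESHOLD,
    crit: CriteriaSet | None = None,
    fit_cfg: FitnessConfig | None = None,
) -> list[CpGIsland]:
    """Apply :func:`merge_pass` to a fixed point (idempotent)."""
    if fit_cfg is None:
        fit_cfg = FitnessConfig() if crit is None else FitnessConfig(criteria=crit)
    if crit is None:
        crit = fit_cfg.criteria
    current = list(islands)
    while True:
        merged = merge_pass(current, seq, gap_threshold, crit, fit_cfg)
        if len(merged) == len(current):
            return merged
        current = merged
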