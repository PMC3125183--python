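"""Sequence containers, windowing and GC / CpG observed-expected statistics.

A CpG island in the Gardiner-Garden & Frommer (GGF) sense is a stretch of
DNA at least 200 bp long with GC content >= 50% and an observed/expected
CpG dinucleotide ratio >= 0.6, where the expectation assumes independence
of the C and G base frequencies:

    O/E = (#CpG * N) / (#C * #G)

The Takai & Jones (TJ) revision, used when Alu repeats are masked out,
raises the thresholds to 500 bp / 55% / 0.65.

Coordinates are 0-based half-open throughout (BED convention); 1-based
inclusive coordinates appear only in human-readable report text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")

#: Gardiner-Garden & Frommer thresholds: length >= 200 bp, GC >= 50%, O/E >= 0.6.
GGF: "CriteriaSet"
#: Takai & Jones thresholds (Alu-masked mode): length >= 500 bp, GC >= 55%, O/E >= 0.65.
TJ: "CriteriaSet"


class FormatError(ValueError):
    """Malformed input file (FASTA/BED)."""


class CoordinateError(ValueError):
    """Interval lies outside the sequence it is applied to."""


class UndefinedStatistic(ArithmeticError):
    """A composition statistic is undefined (e.g. an all-N interval)."""


@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide string over {A, C, G, T, N}."""

    name: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - VALID_BASES
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)!r} in {self.name!r}")

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.residues)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval [start, end)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class NucleotideCounts:
    """Base and CpG-dinucleotide tallies over an interval; Ns excluded."""

    nA: int
    nT: int
    nC: int
    nG: int
    nCpG: int

    @property
    def N(self) -> int:
        """Number of unambiguous (non-N) bases."""
        return self.nA + self.nT + self.nC + self.nG


@dataclass(frozen=True)
class CriteriaSet:
    """Island-calling thresholds: minimum length, GC fraction and O/E ratio."""

    min_length: int
    min_gc: float
    min_oe: float

    def __post_init__(self) -> None:
        if self.min_length <= 0 or not 0 < self.min_gc < 1 or self.min_oe <= 0:
            raise ValueError(f"invalid criteria {self}")


GGF = CriteriaSet(min_length=200, min_gc=0.50, min_oe=0.60)
TJ = CriteriaSet(min_length=500, min_gc=0.55, min_oe=0.65)


def normalize_residues(raw: str) -> str:
    """Uppercase and map every non-ACGTN character (IUPAC codes etc.) to N."""
    return _NON_ACGTN.sub("N", raw.upper())


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read all records of a FASTA file into :class:`GenomeSequence` objects.

    Mixed/lower case is folded to upper case; ambiguity codes become N.
    """
    path = Path(path)
    with open(path) as handle:
        first = handle.readline()
        if not first.strip():
            raise FormatError(f"{path}: empty FASTA (line 1)")
        if not first.startswith(">"):
            raise FormatError(f"{path}: line 1 is not a FASTA header: {first[:40]!r}")
    records = [
        GenomeSequence(name=rec.id, residues=normalize_residues(str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"{path}: no FASTA records found (line 1)")
    return records


def write_fasta(path: str | Path, seqs: Iterable[GenomeSequence], width: int = 70) -> None:
    with open(path, "w") as out:
        for seq in seqs:
            out.write(f">{seq.name}\n")
            for i in range(0, seq.length, width):
                out.write(seq.residues[i : i + width] + "\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file into a DataFrame (chrom, start, end[, name, score, strand])."""
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=cols[:3])
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED needs >= 3 columns, found {df.shape[1]}")
    df = df.iloc[:, : min(6, df.shape[1])]
    df.columns = cols[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(path: str | Path, df: pd.DataFrame, track_header: str | None = None) -> None:
    with open(path, "w") as out:
        if track_header:
            out.write(track_header.rstrip("\n") + "\n")
        df.to_csv(out, sep="\t", header=False, index=False)


def bed_intervals(df: pd.DataFrame, chrom: str | None = None) -> list[Interval]:
    """Extract Interval objects, optionally restricted to one chromosome."""
    if chrom is not None and len(df):
        df = df[df["chrom"] == chrom]
    return [Interval(int(s), int(e)) for s, e in zip(df["start"], df["end"])]


def partition_windows(seq: GenomeSequence, window_size: int, overlap: int) -> list[Interval]:
    """Tile [0, length) with step ``window_size - overlap``; last window truncated.

    Defaults elsewhere use 10 kb windows with 2 kb overlap so that an island of
    at most 2 kb crossing a seam fits entirely in the overlapped neighbour.
    """
    if overlap < 0 or window_size <= overlap:
        raise ValueError(f"need window_size > overlap >= 0, got {window_size}, {overlap}")
    step = window_size - overlap
    windows: list[Interval] = []
    start = 0
    while True:
        end = min(start + window_size, seq.length)
        windows.append(Interval(start, end))
        if end >= seq.length:
            break
        start += step
    return windows


def _check_bounds(seq: GenomeSequence, iv: Interval) -> None:
    if iv.end > seq.length:
        raise CoordinateError(f"interval [{iv.start},{iv.end}) outside {seq.name!r} (length {seq.length})")


def count_nucleotides(seq: GenomeSequence, iv: Interval) -> NucleotideCounts:
    """Exact base tallies and CpG dimer count for ``iv``; Ns break dimers."""
    _check_bounds(seq, iv)
    sub = seq.residues[iv.start : iv.end]
    return NucleotideCounts(
        nA=sub.count("A"),
        nT=sub.count("T"),
        nC=sub.count("C"),
        nG=sub.count("G"),
        nCpG=sub.count("CG"),
    )


def gc_content(c: NucleotideCounts) -> float:
    """(C+G)/N over unambiguous bases."""
    if c.N == 0:
        raise UndefinedStatistic("GC content of an all-N interval is undefined")
    return (c.nC + c.nG) / c.N


def oe_ratio(c: NucleotideCounts) -> float:
    """GGF observed/expected CpG ratio (#CpG * N) / (#C * #G); 0 if no C or no G."""
    if c.N == 0:
        raise UndefinedStatistic("O/E ratio of an all-N interval is undefined")
    if c.nC == 0 or c.nG == 0:
        return 0.0
    return c.nCpG * c.N / (c.nC * c.nG)


def meets_criteria(iv: Interval, c: NucleotideCounts, crit: CriteriaSet) -> bool:
    """True iff length, GC and O/E all reach their thresholds (inclusive)."""
    if c.N == 0:
        return False
    return (
        iv.length >= crit.min_length
        and gc_content(c) >= crit.min_gc
        and oe_ratio(c) >= crit.min_oe
    )


def mask_intervals(seq: GenomeSequence, mask: Sequence[Interval]) -> GenomeSequence:
    """Replace masked positions with N (coordinates preserved).

    Used for the Alu-masked (TJ criteria) mode: masked bases contribute to
    neither the base counts nor CpG dimers.
    """
    if not mask:
        return seq
    residues = np.frombuffer(seq.residues.encode(), dtype="S1").copy()
    for iv in mask:
        _check_bounds(seq, iv)
        residues[iv.start : iv.end] = b"N"
    return GenomeSequence(name=seq.name, residues=residues.tobytes().decode())


class SequenceProfile:
    """Prefix-sum profile enabling O(1) composition queries over any interval.

    cum_* arrays have length L+1; ``cum_cpg[i]`` counts CpG dimers with start
    position < i that are fully non-N, so dimers inside [s, e) number
    ``cum_cpg[e-1] - cum_cpg[s]``.
    """

    def __init__(self, seq: GenomeSequence):
        self.name = seq.name
        self.length = seq.length
        arr = np.frombuffer(seq.residues.encode(), dtype="S1")
        is_c = arr == b"C"
        is_g = arr == b"G"
        valid = arr != b"N"
        cpg = np.zeros(self.length, dtype=bool)
        if self.length >= 2:
            cpg[:-1] = is_c[:-1] & is_g[1:]
        z = np.zeros(1, dtype=np.int64)
        self.cum_c = np.concatenate([z, np.cumsum(is_c, dtype=np.int64)])
        self.cum_g = np.concatenate([z, np.cumsum(is_g, dtype=np.int64)])
        self.cum_valid = np.concatenate([z, np.cumsum(valid, dtype=np.int64)])
        self.cum_cpg = np.concatenate([z, np.cumsum(cpg, dtype=np.int64)])

    def counts_batch(self, starts: np.ndarray, ends: np.ndarray):
        """Vectorized (nC, nG, nValid, nCpG) for arrays of intervals."""
        s = np.asarray(starts, dtype=np.int64)
        e = np.asarray(ends, dtype=np.int64)
        n_c = self.cum_c[e] - self.cum_c[s]
        n_g = self.cum_g[e] - self.cum_g[s]
        n_valid = self.cum_valid[e] - self.cum_valid[s]
        n_cpg = self.cum_cpg[np.maximum(e - 1, s)] - self.cum_cpg[s]
        return n_c, n_g, n_valid, n_cpg

    def counts(self, iv: Interval) -> tuple[int, int, int, int]:
        n_c, n_g, n_valid, n_cpg = self.counts_batch(
            np.array([iv.start]), np.array([iv.end])
        )
        return int(n_c[0]), int(n_g[0]), int(n_valid[0]), int(n_cpg[0])
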