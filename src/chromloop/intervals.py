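"""Coordinate conventions, interval algebra, loop geometry and shuffling.

All coordinates are 0-based, half-open (BED-native).  Conversions to other
dialects happen only at I/O edges.  A chromatin loop is modelled as two cis
anchors; its *span* runs from the left anchor's start to the right anchor's
end and is the unit of all overlap scoring downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Genome",
    "GenomicInterval",
    "Loop",
    "overlap_bp",
    "merge_intervals",
    "shuffle_intervals",
    "shuffle_loops",
]


@dataclass(frozen=True)
class Genome:
    """Registry of chromosome names and lengths (bp)."""

    chrom_sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        for name, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {size}")

    @property
    def names(self) -> list[str]:
        return list(self.chrom_sizes)

    def size(self, chrom: str) -> int:
        return self.chrom_sizes[chrom]

    def total_bp(self) -> int:
        return sum(self.chrom_sizes.values())


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def shifted(self, chrom: str, start: int) -> "GenomicInterval":
        return replace(self, chrom=chrom, start=start, end=start + self.length)


@dataclass(frozen=True)
class Loop:
    """A cis chromatin interaction between two anchors.

    ``label`` marks differential status of the interaction in the knockout
    ("overinteracting", "underinteracting" or "none").
    """

    left_anchor: GenomicInterval
    right_anchor: GenomicInterval
    qvalue: float | None = None
    label: str = "none"
    name: str = ""

    def __post_init__(self) -> None:
        if self.left_anchor.chrom != self.right_anchor.chrom:
            raise ValueError("loop anchors must be cis (same chromosome)")
        if self.left_anchor.start > self.right_anchor.start:
            raise ValueError("left anchor must not start after right anchor")
        if self.qvalue is not None and not (0.0 <= self.qvalue <= 1.0):
            raise ValueError(f"q-value {self.qvalue} outside [0, 1]")
        if self.label not in ("none", "overinteracting", "underinteracting"):
            raise ValueError(f"unknown loop label {self.label!r}")

    @property
    def chrom(self) -> str:
        return self.left_anchor.chrom

    @property
    def span(self) -> GenomicInterval:
        """Outer coordinates of the two anchors."""
        return GenomicInterval(
            self.chrom, self.left_anchor.start, self.right_anchor.end
        )


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Base pairs shared by two intervals (0 if on different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_intervals(items: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge intervals into sorted, non-overlapping unique regions.

    Book-ended (adjacent) intervals are merged.  Strand and names are
    discarded: the result describes bp coverage only.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in items:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or book-ended
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _placement_capacity(genome: Genome, length: int) -> tuple[list[str], np.ndarray]:
    """Chromosomes that can host an interval of ``length`` and their number
    of valid start positions."""
    names = [n for n, s in genome.chrom_sizes.items() if s >= length]
    caps = np.array([genome.size(n) - length + 1 for n in names], dtype=float)
    return names, caps


def random_placements(
    lengths: Sequence[int],
    genome: Genome,
    rng: np.random.Generator,
    same_chromosome: Sequence[str] | None = None,
) -> tuple[list[str], np.ndarray]:
    """Draw a uniform placement for each length.

    Placement is uniform over all valid (chromosome, start) pairs: a
    chromosome is drawn with probability proportional to its number of valid
    start positions, then a start uniformly among them.  With
    ``same_chromosome`` the i-th item stays on the given chromosome.
    """
    chroms: list[str] = []
    starts = np.empty(len(lengths), dtype=np.int64)
    for i, length in enumerate(lengths):
        if same_chromosome is not None:
            chrom = same_chromosome[i]
            cap = genome.size(chrom) - length + 1
            if cap < 1:
                raise ValueError(
                    f"item of length {length} does not fit on chromosome {chrom}"
                )
            chroms.append(chrom)
            starts[i] = rng.integers(0, cap)
        else:
            names, caps = _placement_capacity(genome, length)
            if not names:
                raise ValueError(
                    f"item of length {length} longer than every chromosome"
                )
            j = rng.choice(len(names), p=caps / caps.sum())
            chroms.append(names[j])
            starts[i] = rng.integers(0, int(caps[j]))
    return chroms, starts


def shuffle_intervals(
    items: Sequence[GenomicInterval],
    genome: Genome,
    seed,
    same_chromosome: bool = False,
) -> list[GenomicInterval]:
    """Randomly re-place each interval, preserving its length.

    Placement is uniform over valid start positions across the whole genome
    (chromosome weighted by capacity); ``same_chromosome=True`` restricts
    each interval to its original chromosome, matching the common
    shuffling-tool default.
    """
    rng = _as_rng(seed)
    lengths = [iv.length for iv in items]
    keep = [iv.chrom for iv in items] if same_chromosome else None
    try:
        chroms, starts = random_placements(lengths, genome, rng, keep)
    except ValueError as exc:
        raise ValueError(f"cannot shuffle intervals: {exc}") from exc
    return [iv.shifted(c, int(s)) for iv, c, s in zip(items, chroms, starts)]


def shuffle_loops(
    loops: Sequence[Loop],
    genome: Genome,
    seed,
    same_chromosome: bool = False,
) -> list[Loop]:
    """Randomly re-place each loop as a rigid unit.

    The span moves as a whole: anchor lengths and the gap between anchors are
    conserved, so shuffled loops remain cis and keep their geometry.
    """
    rng = _as_rng(seed)
    lengths = [lp.span.length for lp in loops]
    keep = [lp.chrom for lp in loops] if same_chromosome else None
    try:
        chroms, starts = random_placements(lengths, genome, rng, keep)
    except ValueError as exc:
        raise ValueError(f"cannot shuffle loops: {exc}") from exc
    out = []
    for lp, chrom, start in zip(loops, chroms, starts):
        shift = int(start) - lp.left_anchor.start
        out.append(
            Loop(
                left_anchor=lp.left_anchor.shifted(chrom, lp.left_anchor.start + shift),
                right_anchor=lp.right_anchor.shifted(
                    chrom, lp.right_anchor.start + shift
                ),
                qvalue=lp.qvalue,
                label=lp.label,
                name=lp.name,
            )
        )
    return out


class IntervalIndex:
    """Per-chromosome sorted arrays supporting fast overlap queries.

    Built from possibly-overlapping intervals; queries use a running-max of
    end coordinates so correctness does not depend on disjointness.
    """

    def __init__(self, items: Sequence[GenomicInterval]):
        self.items = list(items)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[int]] = {}
        for i, iv in enumerate(self.items):
            by_chrom.setdefault(iv.chrom, []).append(i)
        for chrom, idxs in by_chrom.items():
            idx = np.array(idxs)
            starts = np.array([self.items[i].start for i in idxs])
            ends = np.array([self.items[i].end for i in idxs])
            order = np.argsort(starts, kind="stable")
            starts, ends, idx = starts[order], ends[order], idx[order]
            maxend = np.maximum.accumulate(ends)
            self._by_chrom[chrom] = (starts, ends, idx, maxend)

    def overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices (into the original sequence) of intervals overlapping
        [start, end) by >= 1 bp."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return np.array([], dtype=int)
        starts, ends, idx, maxend = entry
        hi = np.searchsorted(starts, end, side="left")
        # candidates before hi whose end > start
        lo = np.searchsorted(maxend, start, side="right")
        sel = slice(lo, hi)
        mask = ends[sel] > start
        return idx[sel][mask]

    def any_overlap(self, chrom: str, start: int, end: int) -> bool:
        return self.overlapping(chrom, start, end).size > 0
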