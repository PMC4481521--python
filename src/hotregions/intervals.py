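"""Genomic coordinate model and interval arithmetic.

All coordinates are 0-based, half-open (BED convention). 1-based inputs
(GWAS catalog positions, GTF records) are converted at the I/O boundary.
Strand is ignored throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "GenomeLayout",
    "Interval",
    "RegionSet",
    "total_length",
    "contains",
    "genome_fraction",
]


class LayoutMismatchError(KeyError):
    """A chromosome name was not found in the genome layout."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered set of chromosomes with their lengths in base pairs."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        for name, length in self.chromosomes:
            if length < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @classmethod
    def from_dict(cls, sizes: dict[str, int]) -> "GenomeLayout":
        return cls(tuple(sizes.items()))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise LayoutMismatchError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_size(self) -> int:
        return sum(length for _, length in self.chromosomes)


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def _merge_sorted(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping/adjacent-overlapping intervals; inputs sorted by start.

    Book-ended intervals (end == next start) are kept separate: they cover
    disjoint bases, so merging them is unnecessary for any downstream count.
    """
    if len(starts) == 0:
        return starts, ends
    out_s = [starts[0]]
    out_e = [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s < out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


class RegionSet:
    """A labelled set of genomic intervals with overlaps merged at construction.

    Optionally carries a per-interval score (e.g. TFBS complexity); when
    overlapping scored intervals merge, the merged interval keeps the maximum
    score of its parts.
    """

    def __init__(
        self,
        intervals: Iterable[Interval],
        label: str = "",
        scores: Optional[Sequence[float]] = None,
    ) -> None:
        self.label = label
        ivs = list(intervals)
        if scores is not None:
            scores = list(scores)
            if len(scores) != len(ivs):
                raise ValueError("scores length does not match intervals")
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for i, iv in enumerate(ivs):
            sc = scores[i] if scores is not None else np.nan
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, sc))

        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._scores: dict[str, np.ndarray] = {}
        for chrom, recs in by_chrom.items():
            recs.sort()
            s = np.array([r[0] for r in recs], dtype=np.int64)
            e = np.array([r[1] for r in recs], dtype=np.int64)
            sc = np.array([r[2] for r in recs], dtype=float)
            ms, me, msc = self._merge_scored(s, e, sc)
            self._starts[chrom] = ms
            self._ends[chrom] = me
            self._scores[chrom] = msc

    @staticmethod
    def _merge_scored(
        s: np.ndarray, e: np.ndarray, sc: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if len(s) == 0:
            return s, e, sc
        out = [[s[0], e[0], sc[0]]]
        for a, b, c in zip(s[1:], e[1:], sc[1:]):
            if a < out[-1][1]:
                out[-1][1] = max(out[-1][1], b)
                prev = out[-1][2]
                if np.isnan(prev):
                    out[-1][2] = c
                elif not np.isnan(c):
                    out[-1][2] = max(prev, c)
            else:
                out.append([a, b, c])
        arr = np.array(out, dtype=float)
        return arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2]

    # -- accessors ---------------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def per_chrom(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays for one chromosome (empty if absent)."""
        empty = np.empty(0, dtype=np.int64)
        return self._starts.get(chrom, empty), self._ends.get(chrom, empty)

    def intervals(self) -> Iterator[Interval]:
        for chrom in self.chroms:
            for s, e in zip(self._starts[chrom], self._ends[chrom]):
                yield Interval(chrom, int(s), int(e))

    def scores(self) -> Iterator[float]:
        for chrom in self.chroms:
            yield from (float(v) for v in self._scores[chrom])

    def __len__(self) -> int:
        return sum(len(v) for v in self._starts.values())

    def __repr__(self) -> str:  # pragma: no cover
        return f"RegionSet({self.label!r}, n={len(self)}, bp={self.total_length})"

    # -- operations --------------------------------------------------------

    @property
    def total_length(self) -> int:
        """Total covered base pairs, Σ(end − start) over merged intervals."""
        return int(
            sum((self._ends[c] - self._starts[c]).sum() for c in self._starts)
        )

    def contains(self, chrom: str, pos: int) -> bool:
        """True iff some interval satisfies start <= pos < end."""
        if chrom not in self._starts:
            return False
        starts, ends = self._starts[chrom], self._ends[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return bool(i >= 0 and pos < ends[i])

    def contains_positions(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorised membership for an array of positions on one chromosome."""
        positions = np.asarray(positions, dtype=np.int64)
        if chrom not in self._starts:
            return np.zeros(positions.shape, dtype=bool)
        starts, ends = self._starts[chrom], self._ends[chrom]
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        out = np.zeros(positions.shape, dtype=bool)
        out[ok] = positions[ok] < ends[idx[ok]]
        return out

    def genome_fraction(self, genome: GenomeLayout) -> float:
        """Fraction of the genome covered by this set, in [0, 1]."""
        for chrom in self._starts:
            limit = genome.length_of(chrom)
            if self._ends[chrom][-1] > limit:
                raise ValueError(
                    f"region on {chrom} extends past chromosome end ({limit})"
                )
        return self.total_length / genome.total_size

    def complement(self, genome: GenomeLayout) -> "RegionSet":
        """Uncovered portion of the genome (used for sampling outside regions)."""
        gaps: list[Interval] = []
        for chrom, length in genome.chromosomes:
            starts, ends = self.per_chrom(chrom)
            prev = 0
            for s, e in zip(starts, ends):
                if s > prev:
                    gaps.append(Interval(chrom, prev, int(s)))
                prev = int(e)
            if prev < length:
                gaps.append(Interval(chrom, prev, length))
        return RegionSet(gaps, label=f"not-{self.label}")


# Functional aliases matching the operation-level vocabulary.

def total_length(regions: RegionSet) -> int:
    return regions.total_length


def contains(regions: RegionSet, chrom: str, pos: int, genome: GenomeLayout | None = None) -> bool:
    if genome is not None and chrom not in genome.names:
        raise LayoutMismatchError(f"unknown chromosome {chrom!r}")
    return regions.contains(chrom, pos)


def genome_fraction(regions: RegionSet, genome: GenomeLayout) -> float:
    return regions.genome_fraction(genome)
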