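"""Genomic intervals, BED-family I/O, and the accessible-region universe.

Coordinates are BED convention throughout: 0-based, half-open ``[start, end)``.
The "universe" of chromatin accessible regions (ChARs) is the union of peak
calls across all biological conditions with overlapping regions merged; it is
the common row space every downstream count and annotation keys into.
"""

from __future__ import annotations

import gzip
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "PeakUniverse",
    "read_bed",
    "write_bed",
    "merge_intervals",
    "build_universe",
    "subtract_blacklist",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic region ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class PeakSet:
    """Peak calls for one biological condition, kept coordinate-sorted."""

    condition_label: str
    intervals: list[GenomicInterval]

    def __post_init__(self) -> None:
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )

    def __len__(self) -> int:
        return len(self.intervals)


class PeakUniverse:
    """Merged, ID-stable region universe.

    Regions are pairwise non-overlapping within a chromosome and sorted by
    (chrom, start); region IDs are ``chrom:start-end`` strings derived from
    the final merged coordinates.
    """

    def __init__(self, regions: Sequence[GenomicInterval]):
        regs = sorted(regions, key=lambda iv: (iv.chrom, iv.start))
        for a, b in zip(regs, regs[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(
                    f"universe regions overlap: {a.region_id} / {b.region_id}"
                )
        self.regions: list[GenomicInterval] = regs
        self.region_ids: list[str] = [iv.region_id for iv in regs]
        # per-chromosome sorted arrays for binary search
        self._chrom_index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for i, iv in enumerate(regs):
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, i))
        for chrom, triples in by_chrom.items():
            starts = np.array([t[0] for t in triples], dtype=np.int64)
            ends = np.array([t[1] for t in triples], dtype=np.int64)
            idx = np.array([t[2] for t in triples], dtype=np.int64)
            self._chrom_index[chrom] = (starts, ends, idx)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def query_point(self, chrom: str, pos: int) -> int | None:
        """Index of the unique region containing ``pos``, or None."""
        entry = self._chrom_index.get(chrom)
        if entry is None:
            return None
        starts, ends, idx = entry
        j = int(np.searchsorted(starts, pos, side="right")) - 1
        if j >= 0 and pos < ends[j]:
            return int(idx[j])
        return None

    def query_points(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorised point lookup; -1 where no region contains the point."""
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(positions.shape, -1, dtype=np.int64)
        entry = self._chrom_index.get(chrom)
        if entry is None:
            return out
        starts, ends, idx = entry
        j = np.searchsorted(starts, positions, side="right") - 1
        ok = (j >= 0) & (positions < ends[np.clip(j, 0, len(ends) - 1)])
        out[ok] = idx[j[ok]]
        return out

    def query_interval(self, interval: GenomicInterval) -> int | None:
        """Index of the region fully containing ``interval``, or None."""
        i = self.query_point(interval.chrom, interval.start)
        if i is not None and self.regions[i].contains(interval):
            return i
        return None


def _open_text(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


_DIALECT_MIN_FIELDS = {"bed3": 3, "bed6": 3, "narrowPeak": 10}


def read_bed(path: str, dialect: str = "bed3") -> PeakSet:
    """Read a BED3/BED6/narrowPeak file into a sorted :class:`PeakSet`.

    Comment (``#``), ``track`` and ``browser`` lines are skipped.  Coordinates
    are taken verbatim (BED files are already 0-based half-open).  narrowPeak
    columns beyond name/strand (signal, p, q, summit) are parsed for format
    validation but not retained.
    """
    if dialect not in _DIALECT_MIN_FIELDS:
        raise ValueError(f"unknown BED dialect {dialect!r}")
    min_fields = _DIALECT_MIN_FIELDS[dialect]
    intervals: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < min_fields:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {min_fields} tab-separated "
                    f"fields for {dialect}, got {len(parts)}"
                )
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinate: {exc}"
                ) from None
            if start >= end or start < 0:
                raise ValueError(
                    f"{path}:{lineno}: invalid coordinates {start} >= {end}"
                )
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            intervals.append(GenomicInterval(chrom, start, end, name, strand))
    return PeakSet(condition_label="", intervals=intervals)


def write_bed(intervals: Iterable[GenomicInterval], path: str) -> None:
    """Write intervals as BED4 (chrom, start, end, name-or-region_id)."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else iv.region_id
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Merge overlapping or bookended intervals per chromosome.

    Two intervals merge iff they overlap or touch (gap 0).  The union of
    covered bases is preserved; output is sorted and non-overlapping.
    """
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(
                    iv.chrom, merged[-1].start, iv.end
                )
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def build_universe(peaksets: Sequence[PeakSet]) -> PeakUniverse:
    """The peak universe: merged union of peaks across all conditions."""
    if not peaksets:
        raise ValueError("build_universe requires at least one PeakSet")
    all_peaks = [iv for ps in peaksets for iv in ps.intervals]
    if not all_peaks:
        raise ValueError(
            "all input PeakSets are empty: an empty universe is unusable"
        )
    return PeakUniverse(merge_intervals(all_peaks))


def subtract_blacklist(
    universe: PeakUniverse, blacklist: Sequence[GenomicInterval]
) -> PeakUniverse:
    """Optional region-level blacklist subtraction.

    Drops every universe region overlapping a blacklist interval by >= 1 bp.
    Off by default in the pipeline: the standard filter removes blacklisted
    reads, not regions.
    """
    black = merge_intervals(blacklist)
    kept = [
        r for r in universe.regions if not any(r.overlaps(b) for b in black)
    ]
    if not kept:
        raise ValueError("blacklist subtraction removed every universe region")
    return PeakUniverse(kept)
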