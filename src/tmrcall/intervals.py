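"""Genomic intervals and plain-text interval-track input.

All coordinates in this package are 0-based half-open ``[start, end)``.
BED and bedGraph files are read as-is (they already use that convention);
GTF input is converted on the way in (see :mod:`tmrcall.annotation`).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "GenomicInterval",
    "read_interval_track",
    "write_interval_track",
    "total_overlap_bp",
    "merge_intervals",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` with optional strand and score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: Optional[float] = None
    name: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shifted_to(self, start: int) -> "GenomicInterval":
        return replace(self, start=start, end=start + self.length)


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_interval_track(path) -> list[GenomicInterval]:
    """Read a BED3+/bedGraph file into a sorted interval list.

    Column 4 is taken as a name when non-numeric (BED) or as a score when
    numeric (bedGraph); BED6 ``score``/``strand`` columns are kept when
    present.  Overlapping intervals are kept as-is; downstream operations
    define their own overlap semantics.
    """
    intervals: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start ({start}, {end})")
            name: Optional[str] = None
            score: Optional[float] = None
            strand = "."
            if len(fields) >= 4:
                try:
                    score = float(fields[3])
                except ValueError:
                    name = fields[3]
            if len(fields) >= 5 and score is None:
                try:
                    score = float(fields[4])
                except ValueError:
                    pass
            if len(fields) >= 6 and fields[5] in ("+", "-", "."):
                strand = fields[5]
            intervals.append(
                GenomicInterval(chrom, start, end, strand=strand, score=score, name=name)
            )
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return intervals


def write_interval_track(intervals: Iterable[GenomicInterval], path, header: Optional[str] = None) -> None:
    """Write intervals as BED (name present) or bedGraph (score present)."""
    with open(path, "wt") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"#{line}\n")
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None:
                cols.append(iv.name)
                cols.append("0" if iv.score is None else f"{iv.score:g}")
                cols.append(iv.strand)
            elif iv.score is not None:
                cols.append(f"{iv.score:g}")
            fh.write("\t".join(cols) + "\n")


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals per chromosome (scores dropped)."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda i: (i.chrom, i.start, i.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def total_overlap_bp(query: Iterable[GenomicInterval], annotation: Sequence[GenomicInterval]) -> int:
    """Total base pairs of overlap between query intervals and a merged annotation.

    The annotation is merged first so bases covered by several annotation
    records are counted once per query base.
    """
    merged = merge_intervals(annotation)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    import bisect

    total = 0
    for q in query:
        anns = by_chrom.get(q.chrom)
        if not anns:
            continue
        starts = [a.start for a in anns]
        idx = bisect.bisect_right(starts, q.start) - 1
        idx = max(idx, 0)
        for a in anns[idx:]:
            if a.start >= q.end:
                break
            total += q.overlap_bp(a)
    return total


def covered_fraction(query: GenomicInterval, intervals: Sequence[GenomicInterval]) -> float:
    """Fraction of the query's bases covered by the (merged) interval set."""
    return total_overlap_bp([query], list(intervals)) / query.length


def iter_uncovered(query: GenomicInterval, intervals: Sequence[GenomicInterval]) -> Iterator[GenomicInterval]:
    """Yield sub-intervals of the query not covered by the interval set."""
    merged = [iv for iv in merge_intervals(intervals) if iv.chrom == query.chrom]
    cursor = query.start
    for iv in merged:
        if iv.end <= cursor or iv.start >= query.end:
            continue
        if iv.start > cursor:
            yield GenomicInterval(query.chrom, cursor, iv.start)
        cursor = max(cursor, iv.end)
    if cursor < query.end:
        yield GenomicInterval(query.chrom, cursor, query.end)
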