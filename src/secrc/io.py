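"""Readers, writers and interval arithmetic for BED-family formats.

Every coordinate in the package is 0-based half-open (BED convention).
Chromosome names are passed through verbatim: a ``chr1`` vs ``1`` mismatch
between two inputs surfaces as zero overlap plus a logged warning, never as
a silent rename. Strand is carried but ignored by interval arithmetic
(H3K27ac coverage and chromatin loops are unstranded).

Supported dialects: BED3/BED6, ENCODE narrowPeak (10 columns) and broadPeak
(9 columns), 4-column bedGraph, BEDPE (>=6 columns), JASPAR PFM text (see
:mod:`secrc.motifs`), and plain TSV/CSV tables (read with pandas by the
modules that consume them).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "ValidationError",
    "GenomicRegion",
    "RegionSet",
    "SignalTrack",
    "Loop",
    "read_regions",
    "write_regions",
    "read_signal",
    "read_bedpe",
    "write_bedpe",
    "overlap_length",
    "overlap_fraction",
]


class ParseError(ValueError):
    """A line of an input file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """Parsed values violate a domain invariant (e.g. start >= end)."""


_SKIP_PREFIXES = ("#", "track", "browser")


@dataclass(frozen=True)
class GenomicRegion:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``summit``, when present, is the offset of the peak summit from
    ``start`` (narrowPeak column 10); it must fall inside the interval.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."
    summit: int | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("region with empty chromosome name")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")
        if self.summit is not None and not (0 <= self.summit < self.end - self.start):
            raise ValidationError(
                f"summit offset {self.summit} outside {self.chrom}:"
                f"{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def overlaps(self, other: "GenomicRegion") -> bool:
        return overlap_length(self, other) > 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap_length(a: GenomicRegion, b: GenomicRegion) -> int:
    """Length in bp of the intersection of two regions (0 if disjoint)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlap_fraction(a: GenomicRegion, b: GenomicRegion, mode: str = "of_smaller") -> float:
    """Fraction of a reference operand covered by the intersection.

    mode ``of_a``: intersection / len(a); mode ``of_smaller``:
    intersection / min(len(a), len(b)) — the symmetric variant used for
    super-enhancer merging.
    """
    inter = overlap_length(a, b)
    if inter == 0:
        return 0.0
    if mode == "of_a":
        denom = a.length
    elif mode == "of_smaller":
        denom = min(a.length, b.length)
    else:
        raise ValueError(f"unknown overlap mode {mode!r}")
    return inter / denom


class RegionSet:
    """An ordered, sorted collection of regions attributed to one sample."""

    def __init__(self, regions: Iterable[GenomicRegion], sample_id: str = ""):
        self.sample_id = sample_id
        self.regions: list[GenomicRegion] = sorted(regions, key=GenomicRegion.sort_key)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[GenomicRegion]:
        return iter(self.regions)

    def __getitem__(self, i: int) -> GenomicRegion:
        return self.regions[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.regions == other.regions and self.sample_id == other.sample_id

    def chromosomes(self) -> list[str]:
        return sorted({r.chrom for r in self.regions})

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"RegionSet({self.sample_id!r}, n={len(self)})"


@dataclass(frozen=True)
class Loop:
    """A chromatin loop between two anchors, with numeric support."""

    anchor_a: GenomicRegion
    anchor_b: GenomicRegion
    count: float = 1.0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValidationError("loop support count must be >= 0")


class SignalTrack:
    """Piecewise-constant, non-negative coverage over the genome.

    Stored per chromosome as parallel sorted arrays (starts, ends, values);
    intervals must not overlap. This is the container for the
    input-normalized H3K27ac signal summed by super-enhancer scoring.
    """

    def __init__(self, intervals: Iterable[tuple[GenomicRegion, float]]):
        by_chrom: dict[str, list[tuple[int, int, float]]] = defaultdict(list)
        for region, value in intervals:
            if value < 0:
                raise ValidationError(
                    f"negative signal value {value} at {region}"
                )
            by_chrom[region.chrom].append((region.start, region.end, float(value)))
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            values = np.array([r[2] for r in rows], dtype=np.float64)
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise ValidationError(
                    f"overlapping signal intervals on {chrom} near position "
                    f"{int(ends[i])}"
                )
            self._data[chrom] = (starts, ends, values)

    def __len__(self) -> int:
        return sum(len(s) for s, _, _ in self._data.values())

    def chromosomes(self) -> list[str]:
        return sorted(self._data)

    def sum_over(self, region: GenomicRegion) -> float:
        """Sum of value x covered-length over ``region`` (0 off-track)."""
        if region.chrom not in self._data:
            return 0.0
        starts, ends, values = self._data[region.chrom]
        # candidate intervals: those with end > region.start and start < region.end
        lo = int(np.searchsorted(ends, region.start, side="right"))
        hi = int(np.searchsorted(starts, region.end, side="left"))
        if lo >= hi:
            return 0.0
        ov = np.minimum(ends[lo:hi], region.end) - np.maximum(starts[lo:hi], region.start)
        ov = np.clip(ov, 0, None)
        return float(np.dot(ov.astype(np.float64), values[lo:hi]))


# ---------------------------------------------------------------------------
# parsing helpers

_DIALECT_COLUMNS = {"bed3": 3, "bed6": 6, "narrowPeak": 10, "broadPeak": 9}


def _data_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line.split("\t")


def _parse_int(text: str, lineno: int, path: str | Path, what: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(f"{path}: line {lineno}: non-integer {what} {text!r}") from None


def _parse_float(text: str, lineno: int, path: str | Path, what: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise ParseError(f"{path}: line {lineno}: non-numeric {what} {text!r}") from None


def read_regions(path: str | Path, format: str = "bed6", sample_id: str = "") -> RegionSet:
    """Read a BED-family file into a sorted :class:`RegionSet`.

    ``format`` is one of ``bed3``, ``bed6``, ``narrowPeak``, ``broadPeak``.
    Comment/track/browser lines are skipped. Each data line must carry
    exactly the column count of the declared dialect; the narrowPeak summit
    column is captured (``-1`` meaning absent).
    """
    if format not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown region format {format!r}")
    ncol = _DIALECT_COLUMNS[format]
    regions = []
    for lineno, fields in _data_lines(path):
        if len(fields) != ncol:
            raise ParseError(
                f"{path}: line {lineno}: expected {ncol} columns for "
                f"{format}, found {len(fields)}"
            )
        chrom = fields[0]
        start = _parse_int(fields[1], lineno, path, "start")
        end = _parse_int(fields[2], lineno, path, "end")
        name = score = None
        strand = "."
        summit = None
        if ncol >= 6:
            name = fields[3] or None
            score = _parse_float(fields[4], lineno, path, "score") if fields[4] not in (".", "") else None
            strand = fields[5] if fields[5] else "."
        if format == "narrowPeak":
            peak = _parse_int(fields[9], lineno, path, "summit offset")
            summit = None if peak < 0 else peak
        try:
            regions.append(
                GenomicRegion(chrom, start, end, name=name, score=score,
                              strand=strand, summit=summit)
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {lineno}: {exc}") from None
    return RegionSet(regions, sample_id=sample_id or Path(path).stem)


def write_regions(regions: Iterable[GenomicRegion], path: str | Path,
                  format: str = "bed6") -> None:
    if format not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown region format {format!r}")
    with open(path, "w") as fh:
        for r in regions:
            if format == "bed3":
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
                continue
            name = r.name if r.name is not None else "."
            score = f"{r.score:g}" if r.score is not None else "0"
            base = f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{score}\t{r.strand}"
            if format == "bed6":
                fh.write(base + "\n")
            elif format == "broadPeak":
                fh.write(base + "\t0\t-1\t-1\n")
            else:  # narrowPeak
                summit = r.summit if r.summit is not None else -1
                fh.write(base + f"\t0\t-1\t-1\t{summit}\n")


def read_signal(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`.

    Overlapping intervals within a chromosome and negative values are
    rejected (validation errors); abutting intervals are fine.
    """
    intervals = []
    for lineno, fields in _data_lines(path):
        if len(fields) != 4:
            raise ParseError(
                f"{path}: line {lineno}: expected 4 bedGraph columns, "
                f"found {len(fields)}"
            )
        chrom = fields[0]
        start = _parse_int(fields[1], lineno, path, "start")
        end = _parse_int(fields[2], lineno, path, "end")
        value = _parse_float(fields[3], lineno, path, "value")
        try:
            region = GenomicRegion(chrom, start, end)
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {lineno}: {exc}") from None
        if value < 0:
            raise ValidationError(
                f"{path}: line {lineno}: negative signal value {value}"
            )
        intervals.append((region, value))
    return SignalTrack(intervals)


def write_signal(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chromosomes():
            starts, ends, values = track._data[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedpe(path: str | Path) -> list[Loop]:
    """Read a BEDPE file (>=6 columns) into loops.

    Anchor order is preserved as written. Support count comes from the
    score column (column 8) when present, else defaults to 1.
    """
    loops = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 6:
            raise ParseError(
                f"{path}: line {lineno}: expected >=6 BEDPE columns, "
                f"found {len(fields)}"
            )
        try:
            a = GenomicRegion(
                fields[0],
                _parse_int(fields[1], lineno, path, "startA"),
                _parse_int(fields[2], lineno, path, "endA"),
            )
            b = GenomicRegion(
                fields[3],
                _parse_int(fields[4], lineno, path, "startB"),
                _parse_int(fields[5], lineno, path, "endB"),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {lineno}: {exc}") from None
        count = 1.0
        if len(fields) >= 8 and fields[7] not in (".", ""):
            count = _parse_float(fields[7], lineno, path, "score")
        loops.append(Loop(a, b, count=count))
    return loops


def write_bedpe(loops: Iterable[Loop], path: str | Path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            a, b = lp.anchor_a, lp.anchor_b
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}"
                f"\t.\t{lp.count:g}\n"
            )


def warn_on_chromosome_mismatch(a: Sequence[str], b: Sequence[str],
                                what: str = "inputs") -> None:
    """Log a warning when two inputs share no chromosome names."""
    if a and b and not set(a) & set(b):
        logger.warning(
            "no shared chromosome names between %s (e.g. %r vs %r); "
            "overlaps will all be zero", what, list(a)[:3], list(b)[:3]
        )
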