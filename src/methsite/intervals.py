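"""Genomic intervals, BED and chrom.sizes I/O, and basic interval arithmetic.

Coordinates are 0-based half-open throughout (BED convention): an interval
``[start, end)`` has length ``end - start`` base pairs. Printed genome-browser
ranges such as "chr6: 152,128,500-152,129,000" are ingested as
``start=152128500, end=152129000``.

Chromosome names are matched by exact string comparison; use
:func:`normalize_chrom` explicitly if two inputs disagree about the ``chr``
prefix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

__all__ = [
    "GenomicInterval",
    "ChromSizes",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "flanks",
    "overlap_bp",
    "normalize_chrom",
]

_VALID_STRANDS = {"+", "-", "."}


class BedParseError(ValueError):
    """A malformed line in a BED or chrom.sizes file."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name (non-empty, matched exactly).
    start : int
        0-based inclusive start (>= 0).
    end : int
        0-based exclusive end (> start).
    name : str, optional
        Free-text label (BED column 4).
    strand : str
        One of ``+``, ``-`` or ``.`` (default; methylation signal is
        unstranded, so signal aggregation ignores it).
    """

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of {_VALID_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        """Interval length in bp (``end - start``)."""
        return self.end - self.start

    def center(self) -> int:
        """Anchor position used for center-mode region matrices."""
        return (self.start + self.end) // 2


@dataclass
class ChromSizes:
    """Mapping of chromosome name to total length in bp."""

    sizes: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, length in self.sizes.items():
            if not name:
                raise ValueError("chromosome names must be non-empty")
            if int(length) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self.sizes = {k: int(v) for k, v in self.sizes.items()}

    def __getitem__(self, chrom: str) -> int:
        try:
            return self.sizes[chrom]
        except KeyError:
            raise KeyError(
                f"chromosome {chrom!r} not in sizes (have: {sorted(self.sizes)})"
            ) from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def __iter__(self):
        return iter(self.sizes)

    def items(self):
        return self.sizes.items()

    def __len__(self) -> int:
        return len(self.sizes)

    def validate_interval(self, iv: GenomicInterval) -> None:
        """Raise if *iv* extends beyond its chromosome (or names an unknown one)."""
        length = self[iv.chrom]
        if iv.end > length:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome length {length}"
            )


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix; never applied implicitly."""
    return name[3:] if name.lower().startswith("chr") else name


def read_bed(path: str | Path) -> List[GenomicInterval]:
    """Read BED3/BED4/BED6 into a list of intervals, preserving file order.

    ``track``, ``browser`` and ``#`` comment lines and blank lines are
    skipped. Columns 4 and 6, when present, populate ``name`` and ``strand``.

    Raises
    ------
    BedParseError
        On a non-integer coordinate, ``start >= end``, or fewer than three
        columns; the message names the 1-based line number.
    """
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}, line {lineno}: expected >=3 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"{path}, line {lineno}: non-integer coordinates {fields[1]!r}, {fields[2]!r}"
                ) from None
            name = fields[3] if len(fields) >= 4 else ""
            strand = fields[5] if len(fields) >= 6 and fields[5] in _VALID_STRANDS else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, name=name, strand=strand))
            except ValueError as exc:
                raise BedParseError(f"{path}, line {lineno}: {exc}") from None
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (name ``.`` when empty, score column 0)."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name or "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    """Read a two-column ``chrom.sizes`` TSV (name, length)."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise BedParseError(f"{path}, line {lineno}: expected 2 columns")
            name = fields[0]
            if name in sizes:
                raise BedParseError(f"{path}, line {lineno}: duplicate chromosome {name!r}")
            try:
                sizes[name] = int(fields[1])
            except ValueError:
                raise BedParseError(f"{path}, line {lineno}: non-integer length {fields[1]!r}") from None
    return ChromSizes(sizes)


def write_chrom_sizes(sizes: ChromSizes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def flanks(
    region: GenomicInterval, width: int, sizes: ChromSizes
) -> Tuple[GenomicInterval | None, GenomicInterval | None]:
    """Upstream and downstream flanks of *region*, clipped to the chromosome.

    Returns ``(upstream, downstream)`` where upstream is
    ``[max(0, start - width), start)`` and downstream
    ``[end, min(chrom_length, end + width))``. A side whose clipped flank is
    empty is returned as ``None``.
    """
    if width <= 0:
        raise ValueError(f"width must be positive, got {width}")
    chrom_len = sizes[region.chrom]
    sizes.validate_interval(region)
    up_start = max(0, region.start - width)
    upstream = (
        GenomicInterval(region.chrom, up_start, region.start, name=region.name + "_up" if region.name else "")
        if up_start < region.start
        else None
    )
    down_end = min(chrom_len, region.end + width)
    downstream = (
        GenomicInterval(region.chrom, region.end, down_end, name=region.name + "_down" if region.name else "")
        if region.end < down_end
        else None
    )
    return upstream, downstream


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of base pairs shared by two intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))
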