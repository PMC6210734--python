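"""Binned genome-wide signal tracks and region-centered aggregation.

This module re-implements the standard coverage-heatmap machinery used to
profile 5-methylcytosine (5mC) immunoprecipitation signal and CpG density
around sets of genomic regions: a binned :class:`CoverageTrack` per
chromosome, reads-per-million (RPM) normalization, a region-by-relative-bin
:class:`RegionMatrix` (the matrix underlying a heatmap), and its column-wise
average profile.

Missing data is an explicit ``NaN`` sentinel, never zero: a bin with no
bedGraph record is distinguishable from a bin with zero coverage, and means
ignore missing bins.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .intervals import ChromSizes, GenomicInterval

__all__ = [
    "CoverageTrack",
    "RegionMatrix",
    "read_bedgraph",
    "write_bedgraph",
    "rpm_normalize",
    "mean_signal",
    "region_matrix",
    "average_profile",
    "cpg_density_track",
    "region_means",
]

#: recognised units tags for CoverageTrack
UNITS = ("raw", "rpm", "cpg", "fraction")


@dataclass
class CoverageTrack:
    """Per-chromosome binned signal.

    Attributes
    ----------
    bin_size : int
        Bin width in bp; every chromosome's vector has
        ``ceil(chrom_length / bin_size)`` entries.
    data : dict of str to ndarray
        One float vector per chromosome; ``NaN`` marks missing bins.
    units : str
        One of ``raw`` (read counts), ``rpm``, ``cpg`` (CpG dinucleotides
        per bin) or ``fraction`` (methylation level in [0, 1]).
    """

    bin_size: int
    data: Dict[str, np.ndarray] = field(default_factory=dict)
    units: str = "raw"

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.units not in UNITS:
            raise ValueError(f"units must be one of {UNITS}, got {self.units!r}")
        self.data = {c: np.asarray(v, dtype=float) for c, v in self.data.items()}
        if self.units == "fraction":
            for chrom, vec in self.data.items():
                finite = vec[np.isfinite(vec)]
                if finite.size and (finite.min() < 0 or finite.max() > 1):
                    raise ValueError(f"fraction track on {chrom} outside [0, 1]")

    def n_bins(self, chrom: str) -> int:
        return len(self.data[chrom])

    @classmethod
    def empty(cls, sizes: ChromSizes, bin_size: int, units: str = "raw") -> "CoverageTrack":
        data = {
            chrom: np.full(math.ceil(length / bin_size), np.nan)
            for chrom, length in sizes.items()
        }
        return cls(bin_size=bin_size, data=data, units=units)


@dataclass
class RegionMatrix:
    """Rows = regions (input order), columns = bins relative to an anchor.

    In ``center`` mode the anchor is ``floor((start + end) / 2)`` and columns
    tile ``[anchor - upstream, anchor + downstream)`` in ``bin_size`` steps.
    In ``scaled-body`` mode, ``body_bins`` extra columns linearly rescale the
    region body between the upstream and downstream flank columns.
    """

    values: np.ndarray
    bin_size: int
    upstream: int
    downstream: int
    mode: str = "center"
    body_bins: int = 0
    region_names: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.upstream + self.downstream) // self.bin_size + (
            self.body_bins if self.mode == "scaled-body" else 0
        )
        if self.values.ndim != 2 or self.values.shape[1] != expected:
            raise ValueError(
                f"matrix has {self.values.shape[1] if self.values.ndim == 2 else '?'} "
                f"columns, expected {expected}"
            )

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def column_positions(self) -> np.ndarray:
        """Representative relative position (bp) of each column.

        Center mode: offset of the column's left edge from the anchor.
        Scaled-body mode: flank columns as bp offsets from the region edges;
        body columns are numbered 0..body_bins-1 in between (unitless).
        """
        n_up = self.upstream // self.bin_size
        n_down = self.downstream // self.bin_size
        up = np.arange(-n_up, 0) * self.bin_size
        if self.mode == "center":
            down = np.arange(0, n_down) * self.bin_size
            return np.concatenate([up, down])
        body = np.arange(self.body_bins)
        down = np.arange(0, n_down) * self.bin_size
        return np.concatenate([up, body, down])

    def to_tsv(self, path: str | Path) -> None:
        """Serialize as TSV with a JSON header line carrying the metadata."""
        header = {
            "bin_size": self.bin_size,
            "upstream": self.upstream,
            "downstream": self.downstream,
            "mode": self.mode,
            "body_bins": self.body_bins,
            "n_regions": self.n_regions,
        }
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(header) + "\n")
            for i in range(self.n_regions):
                name = self.region_names[i] if i < len(self.region_names) else f"region_{i}"
                row = "\t".join("nan" if not np.isfinite(v) else f"{v:.6g}" for v in self.values[i])
                fh.write(f"{name}\t{row}\n")


def read_bedgraph(path: str | Path, sizes: ChromSizes, bin_size: int) -> CoverageTrack:
    """Bin a 4-column bedGraph into a :class:`CoverageTrack`.

    Each bin's value is the coverage-weighted mean of the bedGraph records
    overlapping it; bins with no record are ``NaN``.

    Raises
    ------
    ValueError
        If a record extends beyond its chromosome end (the message names the
        offending record).
    """
    wsum: Dict[str, np.ndarray] = {}
    wtot: Dict[str, np.ndarray] = {}
    for chrom, length in sizes.items():
        n = math.ceil(length / bin_size)
        wsum[chrom] = np.zeros(n)
        wtot[chrom] = np.zeros(n)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}, line {lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in sizes:
                raise ValueError(f"{path}, line {lineno}: unknown chromosome {chrom!r}")
            if end > sizes[chrom] or start < 0 or start >= end:
                raise ValueError(
                    f"{path}, line {lineno}: record {chrom}:{start}-{end} outside chromosome bounds"
                )
            first, last = start // bin_size, (end - 1) // bin_size
            for b in range(first, last + 1):
                ov = min(end, (b + 1) * bin_size) - max(start, b * bin_size)
                wsum[chrom][b] += ov * value
                wtot[chrom][b] += ov
    data = {}
    for chrom in sizes:
        with np.errstate(invalid="ignore"):
            vec = wsum[chrom] / wtot[chrom]
        vec[wtot[chrom] == 0] = np.nan
        data[chrom] = vec
    return CoverageTrack(bin_size=bin_size, data=data, units="raw")


def write_bedgraph(track: CoverageTrack, sizes: ChromSizes, path: str | Path) -> None:
    """Write one record per non-missing bin (last bin clipped to chrom end)."""
    with open(path, "w") as fh:
        for chrom, vec in track.data.items():
            length = sizes[chrom]
            for b, v in enumerate(vec):
                if not np.isfinite(v):
                    continue
                start = b * track.bin_size
                end = min(length, start + track.bin_size)
                fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")


def rpm_normalize(track: CoverageTrack, library_size: float) -> CoverageTrack:
    """Scale a raw-count track to reads per million mapped reads.

    Every value is multiplied by ``1e6 / library_size``; missing bins stay
    missing. The returned track is tagged ``rpm``.
    """
    if library_size <= 0:
        raise ValueError(f"library_size must be positive, got {library_size}")
    factor = 1e6 / library_size
    data = {chrom: vec * factor for chrom, vec in track.data.items()}
    return CoverageTrack(bin_size=track.bin_size, data=data, units="rpm")


def _window_mean(vec: np.ndarray, bin_size: int, start: int, end: int) -> float:
    """Length-weighted mean of bin values over [start, end), NaN bins ignored."""
    first, last = start // bin_size, (end - 1) // bin_size
    bins = np.arange(first, last + 1)
    lo = np.maximum(start, bins * bin_size)
    hi = np.minimum(end, (bins + 1) * bin_size)
    w = (hi - lo).astype(float)
    v = vec[first : last + 1]
    ok = np.isfinite(v)
    if not ok.any():
        return float("nan")
    return float(np.sum(w[ok] * v[ok]) / np.sum(w[ok]))


def mean_signal(track: CoverageTrack, region: GenomicInterval, sizes: ChromSizes | None = None) -> float:
    """Length-weighted mean signal over *region*, ignoring missing bins.

    Returns ``NaN`` when every overlapped bin is missing. Raises ``KeyError``
    for an unknown chromosome and ``ValueError`` when the region exceeds the
    track's extent.
    """
    if region.chrom not in track.data:
        raise KeyError(f"chromosome {region.chrom!r} not in track")
    vec = track.data[region.chrom]
    if region.end > len(vec) * track.bin_size:
        raise ValueError(f"region {region.chrom}:{region.start}-{region.end} beyond track extent")
    return _window_mean(vec, track.bin_size, region.start, region.end)


def region_means(track: CoverageTrack, regions: Sequence[GenomicInterval]) -> np.ndarray:
    """Vector of :func:`mean_signal` values, one per region (order kept)."""
    return np.array([mean_signal(track, r) for r in regions])


def region_matrix(
    track: CoverageTrack,
    regions: Sequence[GenomicInterval],
    upstream: int,
    downstream: int,
    mode: str = "center",
    body_bins: int = 0,
) -> RegionMatrix:
    """Region-by-relative-bin signal matrix (the matrix behind a heatmap).

    Parameters
    ----------
    upstream, downstream : int
        Extents in bp; must be multiples of the track's bin size.
    mode : {"center", "scaled-body"}
        ``center`` anchors columns at ``floor((start+end)/2)``;
        ``scaled-body`` adds ``body_bins`` columns linearly rescaling the
        region body between the flanks.

    Windows extending beyond the chromosome are set to the missing sentinel.
    """
    if not regions:
        raise ValueError("region collection is empty")
    if mode not in ("center", "scaled-body"):
        raise ValueError(f"unknown mode {mode!r}")
    bs = track.bin_size
    if upstream % bs or downstream % bs:
        raise ValueError("upstream/downstream must be multiples of bin_size")
    if mode == "scaled-body" and body_bins <= 0:
        raise ValueError("scaled-body mode requires body_bins > 0")
    n_up, n_down = upstream // bs, downstream // bs
    n_cols = n_up + n_down + (body_bins if mode == "scaled-body" else 0)
    out = np.full((len(regions), n_cols), np.nan)
    for i, region in enumerate(regions):
        vec = track.data[region.chrom]
        chrom_span = len(vec) * bs
        if mode == "center":
            left = region.center() - upstream
            starts = left + np.arange(n_cols) * bs
            windows = [(int(s), int(s) + bs) for s in starts]
        else:
            windows = []
            for j in range(n_up):
                s = region.start - upstream + j * bs
                windows.append((s, s + bs))
            L = region.length
            edges = [region.start + round(k * L / body_bins) for k in range(body_bins + 1)]
            for k in range(body_bins):
                windows.append((edges[k], edges[k + 1]))
            for j in range(n_down):
                s = region.end + j * bs
                windows.append((s, s + bs))
        for j, (s, e) in enumerate(windows):
            if s < 0 or e > chrom_span or s >= e:
                continue  # stays missing
            out[i, j] = _window_mean(vec, bs, s, e)
    names = [r.name or f"{r.chrom}:{r.start}-{r.end}" for r in regions]
    return RegionMatrix(
        values=out,
        bin_size=bs,
        upstream=upstream,
        downstream=downstream,
        mode=mode,
        body_bins=body_bins if mode == "scaled-body" else 0,
        region_names=names,
    )


def average_profile(matrix: RegionMatrix) -> np.ndarray:
    """Column-wise mean over non-missing entries; all-missing columns → NaN."""
    if matrix.n_regions == 0:
        raise ValueError("matrix has no rows")
    with np.errstate(invalid="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(matrix.values, axis=0)


def write_profile(matrix: RegionMatrix, path: str | Path) -> None:
    """Write the average profile as two-column TSV (relative position, mean)."""
    prof = average_profile(matrix)
    pos = matrix.column_positions()
    with open(path, "w") as fh:
        fh.write("rel_position\tmean_signal\n")
        for p, v in zip(pos, prof):
            fh.write(f"{p}\t{'nan' if not np.isfinite(v) else f'{v:.6g}'}\n")


def cpg_positions(sequence: str) -> np.ndarray:
    """0-based positions of the C of each CG dinucleotide (case-insensitive)."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype="S1")
    if arr.size < 2:
        return np.array([], dtype=int)
    return np.flatnonzero((arr[:-1] == b"C") & (arr[1:] == b"G"))


def cpg_density_track(
    genome: Mapping[str, str], sizes: ChromSizes, bin_size: int
) -> CoverageTrack:
    """Count CG dinucleotides per bin (assigned to the bin of the first base).

    Case-insensitive; ``N`` bases never form a CG. A CG straddling a bin
    boundary is counted once, in its first base's bin, so the genome-wide
    total is conserved.
    """
    data: Dict[str, np.ndarray] = {}
    for chrom, length in sizes.items():
        seq = genome[chrom]
        if len(seq) != length:
            raise ValueError(
                f"sequence length {len(seq)} for {chrom!r} does not match sizes entry {length}"
            )
        n = math.ceil(length / bin_size)
        pos = cpg_positions(seq)
        counts = np.bincount(pos // bin_size, minlength=n).astype(float)
        data[chrom] = counts
    return CoverageTrack(bin_size=bin_size, data=data, units="cpg")
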