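"""IUPAC motif scanning for hormone-responsive elements with CpG annotation.

Steroid-receptor response elements occur as palindromic full sites and as
half sites; whether a site contains (or neighbors) CpG dinucleotides
determines whether DNA methylation can modulate receptor binding. This module
scans sequences for IUPAC-coded patterns on both strands, counts the CpGs in
and around each hit, and classes each hit's predicted methylation
sensitivity as ``none`` (no CpG), ``single-CpG`` or ``multi-CpG``.

Default patterns follow the steroid-receptor consensus literature — full
site ``RGNACANNNTGTNCY``, half site ``TGTNCY`` — and are plain data the
caller can override.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Sequence

import pandas as pd

from .intervals import GenomicInterval
from .tracks import cpg_positions

__all__ = [
    "MotifPattern",
    "MotifHit",
    "FULL_PRE",
    "HALF_PRE",
    "DEFAULT_PATTERNS",
    "scan",
    "annotate_cpg",
    "scan_region_set",
    "reverse_complement",
]

#: IUPAC nucleotide codes and the concrete bases they match.
IUPAC: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly IUPAC-coded) nucleotide string."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifPattern:
    """An IUPAC-coded motif.

    kind is ``full-PRE`` (palindromic response element), ``half-PRE``
    (half site) or ``custom``.
    """

    identifier: str
    iupac: str
    kind: str = "custom"

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError("pattern must be non-empty")
        bad = set(self.iupac.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC code(s) {sorted(bad)} in pattern {self.iupac!r}")
        object.__setattr__(self, "iupac", self.iupac.upper())

    def __len__(self) -> int:
        return len(self.iupac)


FULL_PRE = MotifPattern("full-PRE", "RGNACANNNTGTNCY", kind="full-PRE")
HALF_PRE = MotifPattern("half-PRE", "TGTNCY", kind="half-PRE")
DEFAULT_PATTERNS = [FULL_PRE, HALF_PRE]


@dataclass(frozen=True)
class MotifHit:
    """One motif match, reported in forward-strand coordinates.

    ``matched_text`` is always the forward-strand sequence under the hit,
    also for minus-strand matches. ``cpg_count``/``sensitivity_class`` are
    filled by :func:`annotate_cpg` (class ``none`` iff the count is zero).
    """

    sequence_id: str
    start: int
    end: int
    strand: str
    matched_text: str
    pattern_id: str = ""
    cpg_count: int = 0
    sensitivity_class: str = "none"


def _iupac_regex(iupac: str) -> re.Pattern:
    # subject N never matches: classes expand to concrete ACGT only
    parts = []
    for code in iupac:
        bases = IUPAC[code]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    # lookahead so overlapping occurrences are all reported
    return re.compile(f"(?=({''.join(parts)}))")


def _classify(count: int) -> str:
    if count == 0:
        return "none"
    return "single-CpG" if count == 1 else "multi-CpG"


def scan(
    sequence: str,
    pattern: MotifPattern,
    strands: str = "both",
    sequence_id: str = "",
) -> List[MotifHit]:
    """All matches of *pattern* in *sequence* under IUPAC semantics.

    Matching is case-insensitive; an ``N`` in the subject never matches.
    Minus-strand hits are found by matching the reverse-complemented pattern
    on the forward strand and reported in forward coordinates. Overlapping
    hits are all reported; a palindromic pattern yields a ``+`` and a ``-``
    hit at the same start. Hits are sorted by start, then strand (``+``
    first).
    """
    if strands not in ("both", "forward"):
        raise ValueError(f"strands must be 'both' or 'forward', got {strands!r}")
    subject = sequence.upper()
    hits: List[MotifHit] = []
    fwd = _iupac_regex(pattern.iupac)
    for m in fwd.finditer(subject):
        s = m.start()
        hits.append(
            MotifHit(sequence_id, s, s + len(pattern), "+", m.group(1), pattern_id=pattern.identifier)
        )
    if strands == "both":
        rev = _iupac_regex(reverse_complement(pattern.iupac))
        for m in rev.finditer(subject):
            s = m.start()
            hits.append(
                MotifHit(sequence_id, s, s + len(pattern), "-", m.group(1), pattern_id=pattern.identifier)
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def annotate_cpg(hit: MotifHit, sequence: str, neighbor_flank: int = 0) -> MotifHit:
    """Fill ``cpg_count`` and ``sensitivity_class`` for a hit.

    Counts CG dinucleotides with at least one base inside
    ``[start - neighbor_flank, end + neighbor_flank)``; the flank captures
    "neighboring" CpGs just outside a half site.
    """
    if hit.start < 0 or hit.end > len(sequence):
        raise IndexError(
            f"hit [{hit.start}, {hit.end}) outside sequence of length {len(sequence)}"
        )
    lo = hit.start - neighbor_flank
    hi = hit.end + neighbor_flank
    # a CG whose first base is at p occupies [p, p+2); it overlaps [lo, hi)
    # iff p >= lo - 1 and p < hi
    pos = cpg_positions(sequence)
    count = int(((pos >= lo - 1) & (pos < hi)).sum())
    return replace(hit, cpg_count=count, sensitivity_class=_classify(count))


def scan_region_set(
    genome: Mapping[str, str],
    regions: Sequence[GenomicInterval],
    patterns: Sequence[MotifPattern] = DEFAULT_PATTERNS,
    neighbor_flank: int = 2,
    strands: str = "both",
) -> pd.DataFrame:
    """Scan genomic regions for motifs; return annotated hits as a table.

    Hit coordinates are lifted to genome coordinates; CpG annotation uses the
    full chromosome sequence so neighboring CpGs just outside the region are
    still counted. Duplicate hits from overlapping regions are deduplicated
    by (chrom, start, strand, pattern).

    Returns a DataFrame with columns ``chrom, start, end, strand, pattern,
    matched_text, cpg_count, sensitivity_class``, sorted by position.
    """
    rows = []
    seen = set()
    for region in regions:
        if region.chrom not in genome:
            raise KeyError(f"no sequence for chromosome {region.chrom!r}")
        chrom_seq = genome[region.chrom]
        if region.end > len(chrom_seq):
            raise IndexError(
                f"region {region.chrom}:{region.start}-{region.end} beyond sequence end"
            )
        sub = chrom_seq[region.start : region.end]
        for pattern in patterns:
            if len(sub) < len(pattern):
                continue
            for hit in scan(sub, pattern, strands=strands, sequence_id=region.chrom):
                g_start = region.start + hit.start
                key = (region.chrom, g_start, hit.strand, pattern.identifier)
                if key in seen:
                    continue
                seen.add(key)
                lifted = replace(hit, start=g_start, end=g_start + len(pattern))
                lifted = annotate_cpg(lifted, chrom_seq, neighbor_flank=neighbor_flank)
                rows.append(
                    {
                        "chrom": region.chrom,
                        "start": lifted.start,
                        "end": lifted.end,
                        "strand": lifted.strand,
                        "pattern": pattern.identifier,
                        "matched_text": lifted.matched_text,
                        "cpg_count": lifted.cpg_count,
                        "sensitivity_class": lifted.sensitivity_class,
                    }
                )
    columns = [
        "chrom", "start", "end", "strand", "pattern",
        "matched_text", "cpg_count", "sensitivity_class",
    ]
    df = pd.DataFrame(rows, columns=columns)
    if len(df):
        df = df.sort_values(["chrom", "start", "strand", "pattern"]).reset_index(drop=True)
    return df


def hits_to_bed(table: pd.DataFrame, path) -> None:
    """Write a hit table as BED6 plus pattern, cpg_count and class columns."""
    with open(path, "w") as fh:
        for _, row in table.iterrows():
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.pattern}\t0\t{row.strand}"
                f"\t{row.cpg_count}\t{row.sensitivity_class}\n"
            )
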