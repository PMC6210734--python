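"""Deterministic quantification arithmetic: peak filtering, qPCR relative
expression (ΔΔCt), immunoprecipitation enrichment ratios, bisulfite clone
methylation matrices, and the unpaired two-tailed t-test.

Conventions
-----------
* Peak q-values are stored on the linear FDR scale in ``(0, 1]``;
  narrowPeak / MACS2 inputs carrying ``-log10(q)`` are converted on read.
* ΔΔCt assumes a PCR amplification efficiency of exactly 2 per cycle unless
  an ``efficiency`` argument says otherwise:
  ``fold = efficiency ** -(ΔCt_sample - ΔCt_calibrator)`` with
  ``ΔCt = mean Ct(target) - mean Ct(reference)``.
* Bisulfite clones are assumed indel-free and pre-aligned to the reference
  amplicon; conversion efficiency is estimated from non-CpG cytosines only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval
from .tracks import cpg_positions

__all__ = [
    "PeakRecord",
    "CloneMethylationMatrix",
    "DataError",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_macs2_xls",
    "filter_peaks",
    "read_ct_table",
    "validate_ct_table",
    "relative_expression",
    "induction_fold",
    "enrichment_relative_to_control",
    "clone_matrix",
    "two_sample_t",
]

CT_COLUMNS = ["sample", "condition", "gene", "replicate", "ct"]


class DataError(ValueError):
    """Missing or inconsistent rows in a quantification input."""


@dataclass(frozen=True)
class PeakRecord:
    """One called peak with its enrichment and FDR q-value (linear scale)."""

    interval: GenomicInterval
    summit_offset: int = 0
    score: float = 0.0
    fold_enrichment: float = 0.0
    q_value: float = 1.0

    def __post_init__(self) -> None:
        if self.fold_enrichment < 0:
            raise ValueError(f"fold_enrichment must be >= 0, got {self.fold_enrichment}")
        if not (0.0 < self.q_value <= 1.0):
            raise ValueError(f"q_value must lie in (0, 1], got {self.q_value}")


def read_narrowpeak(path: str | Path) -> List[PeakRecord]:
    """Read ENCODE narrowPeak (BED6+4).

    Column 7 is the fold enrichment (signalValue), column 9 the
    ``-log10(qValue)`` (``-1`` meaning unavailable, stored as q = 1), column
    10 the summit offset from the peak start.
    """
    peaks: List[PeakRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ValueError(f"{path}, line {lineno}: narrowPeak needs 10 columns, got {len(f)}")
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]), name=f[3],
                                 strand=f[5] if f[5] in "+-." else ".")
            neg_log_q = float(f[8])
            q = 1.0 if neg_log_q < 0 else min(1.0, 10.0 ** (-neg_log_q))
            peaks.append(
                PeakRecord(
                    interval=iv,
                    summit_offset=int(f[9]),
                    score=float(f[4]),
                    fold_enrichment=float(f[6]),
                    q_value=q,
                )
            )
    return peaks


def write_narrowpeak(peaks: Iterable[PeakRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            neg_log_q = -math.log10(p.q_value) if p.q_value < 1.0 else 0.0
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{p.score:g}\t{iv.strand}"
                f"\t{p.fold_enrichment:g}\t0\t{neg_log_q:g}\t{p.summit_offset}\n"
            )


def read_macs2_xls(path: str | Path) -> List[PeakRecord]:
    """Read a MACS2-style peaks table (TSV with header, ``#`` comments).

    Expects columns ``chr, start, end, abs_summit, fold_enrichment,
    -log10(qvalue), name``; MACS2 XLS coordinates are 1-based inclusive and
    are converted to 0-based half-open.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chr", "start", "end", "fold_enrichment", "-log10(qvalue)"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    peaks = []
    for _, row in df.iterrows():
        start0 = int(row["start"]) - 1
        iv = GenomicInterval(str(row["chr"]), start0, int(row["end"]),
                             name=str(row.get("name", "")))
        summit = int(row["abs_summit"]) - 1 - start0 if "abs_summit" in df.columns else 0
        q = min(1.0, 10.0 ** (-float(row["-log10(qvalue)"])))
        peaks.append(
            PeakRecord(
                interval=iv,
                summit_offset=summit,
                score=float(row.get("pileup", 0.0)),
                fold_enrichment=float(row["fold_enrichment"]),
                q_value=q,
            )
        )
    return peaks


def filter_peaks(
    peaks: Sequence[PeakRecord],
    q_max: float = 1e-6,
    min_fold: float = 4.0,
    strict_q: bool = True,
    fold_at_least: bool = True,
) -> List[PeakRecord]:
    """Keep peaks passing both the FDR and the enrichment threshold.

    Defaults: ``q_value < 1e-6`` (strict, as printed) and
    ``fold_enrichment >= 4`` ("4-fold enrichment over input" read as
    at-least). Order is preserved; the operation is idempotent and
    tightening either threshold can only shrink the result.
    """
    if q_max <= 0 or min_fold <= 0:
        raise ValueError("thresholds must be positive")
    q_ok = (lambda q: q < q_max) if strict_q else (lambda q: q <= q_max)
    f_ok = (lambda f: f >= min_fold) if fold_at_least else (lambda f: f > min_fold)
    return [p for p in peaks if q_ok(p.q_value) and f_ok(p.fold_enrichment)]


# ---------------------------------------------------------------- qPCR ΔΔCt


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct table CSV with columns sample, condition, gene, replicate, ct."""
    df = pd.read_csv(path)
    validate_ct_table(df)
    return df


def validate_ct_table(table: pd.DataFrame) -> None:
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise DataError(f"Ct table missing columns {sorted(missing)}")
    if (table["ct"] <= 0).any():
        raise DataError("Ct values must be positive")
    dup = table.duplicated(subset=["sample", "condition", "gene", "replicate"])
    if dup.any():
        row = table[dup].iloc[0]
        raise DataError(
            f"duplicate Ct row for sample={row['sample']!r} condition={row['condition']!r} "
            f"gene={row['gene']!r} replicate={row['replicate']!r}"
        )


def _gene_cts(sub: pd.DataFrame, gene: str, label: str) -> pd.DataFrame:
    rows = sub[sub["gene"] == gene]
    if rows.empty:
        raise DataError(f"no Ct rows for gene {gene!r} in {label}")
    return rows


def _delta_ct(sub: pd.DataFrame, target: str, reference: str, label: str) -> Tuple[float, pd.Series]:
    """Mean ΔCt and per-replicate ΔCt (paired on replicate id) for one unit."""
    tgt = _gene_cts(sub, target, label)
    ref = _gene_cts(sub, reference, label)
    mean_dct = tgt["ct"].mean() - ref["ct"].mean()
    merged = pd.merge(
        tgt[["replicate", "ct"]], ref[["replicate", "ct"]],
        on="replicate", suffixes=("_t", "_r"),
    )
    rep_dct = merged["ct_t"] - merged["ct_r"]
    return float(mean_dct), rep_dct


def relative_expression(
    table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_sample: str,
    condition: Optional[str] = None,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Per-sample expression fold change by the ΔΔCt method.

    ``ΔCt = mean Ct(target) - mean Ct(reference)`` within each sample,
    ``ΔΔCt = ΔCt(sample) - ΔCt(calibrator)``, ``fold = efficiency**(-ΔΔCt)``.
    The dispersion column is the SD over replicate-wise folds (replicates
    paired between target and reference by replicate id).

    Returns a DataFrame indexed by sample with columns ``fold``, ``sd`` and
    ``n_replicates``. The calibrator's fold is exactly 1.
    """
    validate_ct_table(table)
    sub = table if condition is None else table[table["condition"] == condition]
    if sub.empty:
        raise DataError(f"no rows for condition {condition!r}")
    samples = list(dict.fromkeys(sub["sample"]))
    if calibrator_sample not in samples:
        raise DataError(f"calibrator sample {calibrator_sample!r} not in table")
    cal_dct, _ = _delta_ct(
        sub[sub["sample"] == calibrator_sample], target_gene, reference_gene,
        f"calibrator {calibrator_sample!r}",
    )
    rows = []
    for sample in samples:
        unit = sub[sub["sample"] == sample]
        dct, rep_dct = _delta_ct(unit, target_gene, reference_gene, f"sample {sample!r}")
        fold = efficiency ** (-(dct - cal_dct))
        rep_folds = efficiency ** (-(rep_dct - cal_dct))
        sd = float(rep_folds.std(ddof=1)) if len(rep_folds) > 1 else float("nan")
        rows.append({"sample": sample, "fold": fold, "sd": sd, "n_replicates": len(rep_dct)})
    return pd.DataFrame(rows).set_index("sample")


def induction_fold(
    table: pd.DataFrame,
    treated_condition: str,
    vehicle_condition: str,
    target_gene: str,
    reference_gene: str,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Hormone-induction fold change (treated / vehicle) per sample.

    For each sample the vehicle condition of that same sample is the
    calibrator: ``fold = efficiency**-(ΔCt_treated - ΔCt_vehicle)``.
    """
    validate_ct_table(table)
    for cond, what in ((treated_condition, "treated"), (vehicle_condition, "vehicle")):
        if not (table["condition"] == cond).any():
            raise DataError(f"{what} condition {cond!r} has no rows")
    rows = []
    for sample in dict.fromkeys(table["sample"]):
        unit = table[table["sample"] == sample]
        tre = unit[unit["condition"] == treated_condition]
        veh = unit[unit["condition"] == vehicle_condition]
        if tre.empty or veh.empty:
            raise DataError(
                f"sample {sample!r} lacks rows for condition "
                f"{treated_condition!r} or {vehicle_condition!r}"
            )
        dct_t, rep_dct = _delta_ct(tre, target_gene, reference_gene, f"{sample}/{treated_condition}")
        dct_v, _ = _delta_ct(veh, target_gene, reference_gene, f"{sample}/{vehicle_condition}")
        fold = efficiency ** (-(dct_t - dct_v))
        rep_folds = efficiency ** (-(rep_dct - dct_v))
        sd = float(rep_folds.std(ddof=1)) if len(rep_folds) > 1 else float("nan")
        rows.append({"sample": sample, "fold": fold, "sd": sd, "n_replicates": len(rep_dct)})
    return pd.DataFrame(rows).set_index("sample")


def enrichment_relative_to_control(
    ip_signal: float, input_signal: float, control_sample_ratio: float
) -> float:
    """Immunoprecipitation enrichment as fold over a control sample.

    ``(ip / input) / control_sample_ratio`` where ``control_sample_ratio`` is
    the control sample's own ip/input ratio.
    """
    if input_signal <= 0:
        raise ValueError(f"input_signal must be positive, got {input_signal}")
    if control_sample_ratio <= 0:
        raise ValueError(f"control_sample_ratio must be positive, got {control_sample_ratio}")
    return (ip_signal / input_signal) / control_sample_ratio


# ------------------------------------------------------- bisulfite clones


@dataclass
class CloneMethylationMatrix:
    """Per-clone, per-CpG methylation calls from bisulfite clone sequencing.

    ``calls`` is clones x positions with entries ``methylated`` /
    ``unmethylated`` / ``undetermined``. ``fractions`` are per-position
    methylated / (methylated + unmethylated); undetermined calls never enter
    fractions. ``conversion`` per clone is the fraction of non-CpG reference
    cytosines read as T — near 1 for a successful bisulfite conversion.
    """

    cpg_positions: np.ndarray
    calls: pd.DataFrame
    fractions: np.ndarray
    conversion: pd.Series

    @property
    def n_clones(self) -> int:
        return len(self.calls)

    def to_tsv(self, path: str | Path) -> None:
        self.calls.to_csv(path, sep="\t")

    def lollipop(self) -> str:
        """Plain-text lollipop rendering (● methylated, ○ unmethylated, ? undetermined)."""
        glyph = {"methylated": "●", "unmethylated": "○", "undetermined": "?"}
        lines = []
        for clone, row in self.calls.iterrows():
            lines.append(f"{clone}\t" + "".join(glyph[v] for v in row))
        frac = "\t".join(f"{f:.2f}" if np.isfinite(f) else "na" for f in self.fractions)
        lines.append(f"fraction\t{frac}")
        return "\n".join(lines)


def clone_matrix(
    reference: str,
    cpg_offsets: Optional[Sequence[int]] = None,
    clones: Sequence[str] = (),
    clone_names: Optional[Sequence[str]] = None,
) -> CloneMethylationMatrix:
    """Call methylation per clone per CpG from pre-aligned bisulfite clones.

    At each CpG offset (C of a CG in the untreated reference): clone base
    ``C`` → methylated, ``T`` → unmethylated, anything else → undetermined.
    When ``cpg_offsets`` is None they are derived from the reference.
    Conversion efficiency per clone is computed from non-CpG reference Cs
    read as C or T (other bases excluded); a clone with efficiency near 0
    failed conversion and its calls are unreliable.
    """
    if not clones:
        raise ValueError("need at least one clone sequence")
    ref = reference.upper()
    offs = (
        np.asarray(cpg_offsets, dtype=int)
        if cpg_offsets is not None
        else cpg_positions(ref)
    )
    for p in offs:
        if not (0 <= p < len(ref)) or ref[p] != "C":
            raise ValueError(f"offset {p} is not a reference cytosine")
    cpg_set = set(int(p) for p in offs)
    noncpg_c = [i for i, b in enumerate(ref) if b == "C" and i not in cpg_set]
    names = list(clone_names) if clone_names is not None else [f"clone_{i+1}" for i in range(len(clones))]
    call_rows = []
    conv = {}
    for name, clone in zip(names, clones):
        cl = clone.upper()
        if len(cl) != len(ref):
            raise ValueError(
                f"clone {name!r} length {len(cl)} differs from reference length {len(ref)}"
            )
        row = []
        for p in offs:
            base = cl[p]
            row.append(
                "methylated" if base == "C" else "unmethylated" if base == "T" else "undetermined"
            )
        call_rows.append(row)
        as_t = sum(1 for i in noncpg_c if cl[i] == "T")
        as_c = sum(1 for i in noncpg_c if cl[i] == "C")
        conv[name] = as_t / (as_t + as_c) if (as_t + as_c) else float("nan")
    calls = pd.DataFrame(call_rows, index=names, columns=[int(p) for p in offs])
    meth = (calls == "methylated").sum(axis=0).to_numpy(dtype=float)
    unmeth = (calls == "unmethylated").sum(axis=0).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = np.where(meth + unmeth > 0, meth / (meth + unmeth), np.nan)
    return CloneMethylationMatrix(
        cpg_positions=np.asarray(offs, dtype=int),
        calls=calls,
        fractions=fractions,
        conversion=pd.Series(conv),
    )


# -------------------------------------------------------------- statistics


def two_sample_t(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Unpaired two-tailed Student's t-test with pooled variance.

    Degenerate inputs: zero pooled variance with equal means gives
    ``(0.0, 1.0)``; zero variance with unequal means gives ``(±inf, 0.0)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return (math.inf if x.mean() > y.mean() else -math.inf), 0.0
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)
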