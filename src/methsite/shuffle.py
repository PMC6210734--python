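"""Size-preserving genomic shuffle null for region-set methylation.

The test asks whether a set of binding sites carries less (or more) 5mC
signal than expected for regions of the same sizes placed at random in the
genome. Each replicate re-places every region uniformly over all valid start
positions, keeping its length; the mean signal over the shuffled set is one
draw from the empirical null. The empirical p-value uses the add-one
(Phipson & Smyth) convention, so it is never zero and is valid for a finite
number of replicates. A Mann-Whitney U test additionally compares the
per-region observed means against the pooled per-region null means.

Randomness is reproducible and parallelizable: replicate ``r`` derives its
own generator from ``SeedSequence(seed, spawn_key=(r,))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .intervals import ChromSizes, GenomicInterval, overlap_bp
from .tracks import CoverageTrack

__all__ = [
    "ShuffleNullResult",
    "shuffle_intervals",
    "empirical_null_test",
    "mann_whitney_u",
]

DIRECTIONS = ("depletion", "enrichment", "two-sided")


@dataclass
class ShuffleNullResult:
    """Outcome of :func:`empirical_null_test`."""

    observed_mean: float
    null_means: np.ndarray
    n_replicates: int
    empirical_p: float
    direction: str
    mw_u: float
    mw_p: float
    seed: int
    n_regions: int = 0

    def __post_init__(self) -> None:
        self.null_means = np.asarray(self.null_means, dtype=float)
        if len(self.null_means) != self.n_replicates:
            raise ValueError("null_means length must equal n_replicates")
        if not (0.0 < self.empirical_p <= 1.0):
            raise ValueError(f"empirical_p must lie in (0, 1], got {self.empirical_p}")

    def to_dict(self) -> dict:
        return {
            "observed_mean": float(self.observed_mean),
            "n_replicates": int(self.n_replicates),
            "empirical_p": float(self.empirical_p),
            "direction": self.direction,
            "mw_u": float(self.mw_u),
            "mw_p": float(self.mw_p),
            "seed": int(self.seed),
            "n_regions": int(self.n_regions),
            "null_mean_of_means": float(np.nanmean(self.null_means)),
            "null_means": [float(v) for v in self.null_means],
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _draw_starts(
    lengths: np.ndarray, chrom_lengths: np.ndarray, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized placement: chromosome index and start per region.

    Chromosome ``c`` is chosen with probability proportional to its number of
    valid starts ``max(0, L_c - w + 1)`` for a region of length ``w``; the
    start is then uniform over those positions.
    """
    valid = chrom_lengths[None, :] - lengths[:, None] + 1
    valid = np.maximum(valid, 0)
    totals = valid.sum(axis=1)
    if (totals == 0).any():
        w = int(lengths[totals == 0][0])
        raise ValueError(f"region of length {w} is longer than every chromosome")
    cum = np.cumsum(valid, axis=1)
    u = rng.random(len(lengths)) * totals
    chrom_idx = (u[:, None] < cum).argmax(axis=1)
    starts = rng.integers(0, valid[np.arange(len(lengths)), chrom_idx])
    return chrom_idx, starts


def shuffle_intervals(
    regions: Sequence[GenomicInterval],
    sizes: ChromSizes,
    seed,
    same_chromosome: bool = False,
    exclude: Optional[Sequence[GenomicInterval]] = None,
    max_tries: int = 1000,
) -> List[GenomicInterval]:
    """Randomly re-place each region, preserving its length.

    Parameters
    ----------
    seed : int or numpy Generator
        Determinism contract: the same seed yields the same output.
    same_chromosome : bool
        Restrict each region to its original chromosome.
    exclude : sequence of intervals, optional
        Placements overlapping any of these are rejected and redrawn, up to
        ``max_tries`` attempts per region.
    """
    rng = _as_rng(seed)
    chroms = list(sizes)
    chrom_lengths = np.array([sizes[c] for c in chroms], dtype=np.int64)
    lengths = np.array([r.length for r in regions], dtype=np.int64)

    if same_chromosome:
        chrom_idx = np.array([chroms.index(r.chrom) for r in regions])
        n_valid = chrom_lengths[chrom_idx] - lengths + 1
        if (n_valid <= 0).any():
            bad = int(np.flatnonzero(n_valid <= 0)[0])
            raise ValueError(
                f"region {regions[bad].name or bad} does not fit on its chromosome"
            )
        starts = rng.integers(0, n_valid)
    else:
        chrom_idx, starts = _draw_starts(lengths, chrom_lengths, rng)

    out = [
        GenomicInterval(chroms[int(c)], int(s), int(s + w), name=r.name, strand=r.strand)
        for c, s, w, r in zip(chrom_idx, starts, lengths, regions)
    ]
    if exclude:
        for i, iv in enumerate(out):
            tries = 0
            while any(overlap_bp(iv, ex) > 0 for ex in exclude):
                tries += 1
                if tries > max_tries:
                    raise RuntimeError(
                        f"no valid placement for region of length {iv.length} "
                        f"after {max_tries} rejections"
                    )
                if same_chromosome:
                    s = int(rng.integers(0, sizes[iv.chrom] - iv.length + 1))
                    iv = GenomicInterval(iv.chrom, s, s + iv.length, name=iv.name, strand=iv.strand)
                else:
                    ci, st = _draw_starts(
                        np.array([iv.length], dtype=np.int64), chrom_lengths, rng
                    )
                    s = int(st[0])
                    iv = GenomicInterval(chroms[int(ci[0])], s, s + iv.length, name=iv.name, strand=iv.strand)
            out[i] = iv
    return out


class _PrefixTrack:
    """Per-base prefix sums of a binned track for O(1) interval means.

    Missing bins contribute zero weight, so interval means ignore them —
    identical to the length-weighted :func:`methsite.tracks.mean_signal`.
    """

    def __init__(self, track: CoverageTrack):
        self.bin_size = track.bin_size
        self.vsum: Dict[str, np.ndarray] = {}
        self.wsum: Dict[str, np.ndarray] = {}
        self.chroms = list(track.data)
        for chrom, bins in track.data.items():
            per_base = np.repeat(bins, track.bin_size)
            finite = np.isfinite(per_base)
            vals = np.where(finite, per_base, 0.0)
            self.vsum[chrom] = np.concatenate([[0.0], np.cumsum(vals)])
            self.wsum[chrom] = np.concatenate([[0.0], np.cumsum(finite.astype(float))])

    def means(self, chroms: Sequence[str], starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        out = np.empty(len(starts))
        for i, (c, s, e) in enumerate(zip(chroms, starts, ends)):
            v = self.vsum[c][e] - self.vsum[c][s]
            w = self.wsum[c][e] - self.wsum[c][s]
            out[i] = v / w if w > 0 else np.nan
        return out


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> Tuple[float, float]:
    """Mann-Whitney U test (U statistic of *x*, p-value).

    Uses the exact null distribution when both samples have at most 8
    observations and there are no ties across the pooled sample; otherwise the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def empirical_null_test(
    track: CoverageTrack,
    regions: Sequence[GenomicInterval],
    sizes: ChromSizes,
    n_replicates: int = 1000,
    direction: str = "depletion",
    seed: int = 0,
    same_chromosome: bool = False,
    exclude: Optional[Sequence[GenomicInterval]] = None,
    mw_comparison: str = "pooled-regions",
) -> ShuffleNullResult:
    """Permutation test of region-set mean signal against a shuffle null.

    The observed statistic is the mean over regions of each region's
    length-weighted mean signal (every region weighted equally; regions whose
    signal is entirely missing are dropped from the mean). Each of the
    ``n_replicates`` replicates shuffles the whole region set once, preserving
    sizes, and records the same statistic; the empirical p-value is
    ``(1 + #{replicates at least as extreme}) / (1 + n_replicates)``.

    ``direction="depletion"`` counts null means <= observed as at least as
    extreme, ``"enrichment"`` counts >=, and ``"two-sided"`` doubles the
    smaller tail (capped at 1).

    ``mw_comparison`` selects the Mann-Whitney samples: ``"pooled-regions"``
    contrasts per-region observed means against all shuffled per-region means
    pooled; ``"replicate-means"`` contrasts them against the replicate-level
    null means.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not regions:
        raise ValueError("regions collection is empty")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if mw_comparison not in ("pooled-regions", "replicate-means"):
        raise ValueError(f"unknown mw_comparison {mw_comparison!r}")
    for r in regions:
        sizes.validate_interval(r)

    prefix = _PrefixTrack(track)
    obs_region_means = prefix.means(
        [r.chrom for r in regions],
        np.array([r.start for r in regions]),
        np.array([r.end for r in regions]),
    )
    if not np.isfinite(obs_region_means).any():
        raise ValueError("signal is entirely missing over the observed regions")
    observed_mean = float(np.nanmean(obs_region_means))

    chroms = list(sizes)
    chrom_lengths = np.array([sizes[c] for c in chroms], dtype=np.int64)
    lengths = np.array([r.length for r in regions], dtype=np.int64)
    use_fast = exclude is None and not same_chromosome

    null_means = np.empty(n_replicates)
    pooled_null: List[np.ndarray] = []
    for r in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(r,)))
        if use_fast:
            ci, starts = _draw_starts(lengths, chrom_lengths, rng)
            reg_chroms = [chroms[int(c)] for c in ci]
            ends = starts + lengths
        else:
            placed = shuffle_intervals(
                regions, sizes, rng, same_chromosome=same_chromosome, exclude=exclude
            )
            reg_chroms = [p.chrom for p in placed]
            starts = np.array([p.start for p in placed])
            ends = np.array([p.end for p in placed])
        rep_means = prefix.means(reg_chroms, starts, ends)
        with np.errstate(invalid="ignore"):
            null_means[r] = np.nanmean(rep_means) if np.isfinite(rep_means).any() else np.nan
        pooled_null.append(rep_means)

    finite_null = null_means[np.isfinite(null_means)]
    n_eff = len(finite_null)
    p_le = (1 + int(np.sum(finite_null <= observed_mean))) / (1 + n_eff)
    p_ge = (1 + int(np.sum(finite_null >= observed_mean))) / (1 + n_eff)
    if direction == "depletion":
        empirical_p = p_le
    elif direction == "enrichment":
        empirical_p = p_ge
    else:
        empirical_p = min(1.0, 2 * min(p_le, p_ge))

    x = obs_region_means[np.isfinite(obs_region_means)]
    if mw_comparison == "pooled-regions":
        y = np.concatenate(pooled_null)
        y = y[np.isfinite(y)]
    else:
        y = finite_null
    alternative = {"depletion": "less", "enrichment": "greater", "two-sided": "two-sided"}[direction]
    mw_u, mw_p = mann_whitney_u(x, y, alternative=alternative)

    return ShuffleNullResult(
        observed_mean=observed_mean,
        null_means=null_means,
        n_replicates=n_replicates,
        empirical_p=empirical_p,
        direction=direction,
        mw_u=mw_u,
        mw_p=mw_p,
        seed=seed,
        n_regions=len(regions),
    )
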