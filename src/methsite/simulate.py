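"""Synthetic epigenome generator for end-to-end pipeline testing.

Generates, from one seed and explicit parameters, every input the analysis
consumes: a genome with CpG islands and planted receptor-binding sites, a
methylome in which binding sites are CpG-rich yet hypomethylated relative to
their flanks, methylated-DNA immunoprecipitation (MeDIP)-like coverage with
Poisson counting noise, bisulfite clone sequences, and qPCR Ct tables with
knockdown and hormone-induction effects.

The default parameters are the study conditions for every simulation-based
check in this package: 2 chromosomes x 1 Mb, background GC 0.42, 20 CpG
islands of 500-2000 bp at 5x CpG enrichment, 50 binding sites of 400 bp,
methylation fractions background/island/site = 0.7/0.1/0.2, a "PR-loss"
island override of 0.8 (a promoter CpG island gaining methylation when the
receptor is lost), mean read depth 1 per CpG, and 300 bp fragments.

Every artifact is a pure function of (spec, seed): artifact ``k`` draws from
``SeedSequence(spec.seed, spawn_key=(k,))``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import ChromSizes, GenomicInterval, write_bed, write_chrom_sizes
from .tracks import CoverageTrack, cpg_positions, write_bedgraph

__all__ = [
    "SyntheticSpec",
    "SyntheticGenome",
    "generate_genome",
    "simulate_methylome",
    "simulate_medip_coverage",
    "simulate_clones",
    "simulate_ct_table",
    "default_ct_effects",
    "write_dataset",
]

# spawn keys for per-artifact child RNG streams
_KEY_GENOME, _KEY_METHYLOME, _KEY_COVERAGE, _KEY_CLONES, _KEY_CT = range(5)

#: concrete full response-element instance planted in every binding site
#: (matches the full-site consensus RGNACANNNTGTNCY)
PLANTED_SITE_SEQ = "GGAACAGAATGTTCT"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic epigenome.

    All methylation levels are fractions in [0, 1]; lengths in bp.
    ``depth`` is the mean number of immunoprecipitated fragments per fully
    methylated CpG.
    """

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    gc_fraction: float = 0.42
    n_islands: int = 20
    island_length_range: Tuple[int, int] = (500, 2000)
    island_cpg_enrichment: float = 5.0
    n_sites: int = 50
    site_length: int = 400
    # binding sites are CpG-elevated relative to flanks, but mildly enough
    # that hypomethylation (0.2 vs 0.7) still lowers their methylated-CpG
    # content: requires site_cpg_enrichment * meth_site / meth_background < 1
    site_cpg_enrichment: float = 2.0
    meth_background: float = 0.7
    meth_island: float = 0.1
    meth_site: float = 0.2
    meth_island_pr_loss: float = 0.8
    depth: float = 1.0
    fragment_length: int = 300
    bin_size: int = 50
    planted_site_seq: str = PLANTED_SITE_SEQ
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_fraction", "meth_background", "meth_island", "meth_site", "meth_island_pr_loss"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        lo, hi = self.island_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid island length range")
        if self.site_length <= len(self.planted_site_seq):
            raise ValueError("site_length must exceed the planted motif length")
        if self.depth <= 0 or self.fragment_length <= 0 or self.bin_size <= 0:
            raise ValueError("depth, fragment_length and bin_size must be positive")

    def rng(self, key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chrom_lengths"] = dict(self.chrom_lengths)
        d["island_length_range"] = list(self.island_length_range)
        return d


@dataclass
class SyntheticGenome:
    """Generated genome plus its ground truth."""

    sequences: Dict[str, str]
    sizes: ChromSizes
    islands: List[GenomicInterval]
    sites: List[GenomicInterval]


def _background_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


def _cg_emission_prob(gc: float, enrichment: float) -> float:
    """Emission probability q such that total CpG density ~ enrichment x background.

    The emitter produces a CG dinucleotide with probability q, else one
    background base. Total density ~ q/(1+q) (emitted CGs) + d(1-q)^2
    (chance CGs between single-base emissions), with d = (gc/2)^2 the
    background density; q is solved by bisection so this equals
    min(enrichment * d, 0.45). enrichment = 1 gives q = 0 (pure background).
    """
    d = (gc / 2) ** 2
    target = min(enrichment * d, 0.45)
    lo, hi = 0.0, 0.9
    for _ in range(60):
        q = (lo + hi) / 2
        if q / (1 + q) + d * (1 - q) ** 2 < target:
            lo = q
        else:
            hi = q
    return (lo + hi) / 2


def _cpg_rich_fragment(rng: np.random.Generator, length: int, gc: float, enrichment: float) -> np.ndarray:
    """Sequence of given length with CpG density ~ enrichment x background."""
    q = _cg_emission_prob(gc, enrichment)
    out = np.empty(length + 1, dtype="S1")
    i = 0
    while i < length:
        block = min(4096, length - i + 1)
        emit_cg = rng.random(block) < q
        bases = _background_bases(rng, block, gc)
        for k in range(block):
            if i >= length:
                break
            if emit_cg[k] and i + 1 < length:
                out[i], out[i + 1] = b"C", b"G"
                i += 2
            else:
                out[i] = bases[k]
                i += 1
    return out[:length]


def _place_nonoverlapping(
    rng: np.random.Generator,
    lengths: Sequence[int],
    sizes: ChromSizes,
    taken: List[GenomicInterval],
    max_tries: int = 10_000,
) -> List[GenomicInterval]:
    chroms = list(sizes)
    chrom_len = np.array([sizes[c] for c in chroms], dtype=np.int64)
    placed: List[GenomicInterval] = []
    occupied = list(taken)
    for w in lengths:
        valid = np.maximum(chrom_len - w + 1, 0)
        if valid.sum() == 0:
            raise ValueError(f"feature of length {w} does not fit in the genome")
        for attempt in range(max_tries):
            u = rng.random() * valid.sum()
            ci = int(np.searchsorted(np.cumsum(valid), u, side="right"))
            s = int(rng.integers(0, valid[ci]))
            cand = GenomicInterval(chroms[ci], s, s + w)
            if all(
                cand.chrom != o.chrom or cand.end <= o.start or o.end <= cand.start
                for o in occupied
            ):
                placed.append(cand)
                occupied.append(cand)
                break
        else:
            raise ValueError(
                "could not place all islands/sites without overlap; "
                "genome too small for the requested features"
            )
    return placed


def generate_genome(spec: SyntheticSpec) -> SyntheticGenome:
    """Generate the genome: background sequence, CpG islands, binding sites.

    Islands and binding sites are placed by rejection sampling so that no two
    features overlap. Both are rewritten with elevated CpG dinucleotide
    frequency (binding sites are CpG-rich relative to their flanks, the
    feature the methylation contrast is measured against), and one concrete
    response-element instance is planted at each site's center.
    """
    rng = spec.rng(_KEY_GENOME)
    sizes = ChromSizes(dict(spec.chrom_lengths))
    seqs: Dict[str, np.ndarray] = {
        chrom: _background_bases(rng, length, spec.gc_fraction)
        for chrom, length in sizes.items()
    }
    island_lengths = rng.integers(
        spec.island_length_range[0], spec.island_length_range[1] + 1, size=spec.n_islands
    )
    islands = _place_nonoverlapping(rng, [int(w) for w in island_lengths], sizes, [])
    islands = [
        GenomicInterval(iv.chrom, iv.start, iv.end, name=f"island_{i}")
        for i, iv in enumerate(islands)
    ]
    sites = _place_nonoverlapping(rng, [spec.site_length] * spec.n_sites, sizes, islands)
    sites = [
        GenomicInterval(iv.chrom, iv.start, iv.end, name=f"site_{i}")
        for i, iv in enumerate(sites)
    ]
    for iv in islands:
        seqs[iv.chrom][iv.start : iv.end] = _cpg_rich_fragment(
            rng, iv.length, spec.gc_fraction, spec.island_cpg_enrichment
        )
    motif = np.frombuffer(spec.planted_site_seq.encode(), dtype="S1")
    for iv in sites:
        seqs[iv.chrom][iv.start : iv.end] = _cpg_rich_fragment(
            rng, iv.length, spec.gc_fraction, spec.site_cpg_enrichment
        )
        m0 = iv.center() - len(motif) // 2
        seqs[iv.chrom][m0 : m0 + len(motif)] = motif
    sequences = {c: a.tobytes().decode("ascii") for c, a in seqs.items()}
    return SyntheticGenome(sequences=sequences, sizes=sizes, islands=islands, sites=sites)


def _feature_mask(length: int, features: Sequence[GenomicInterval], chrom: str) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for iv in features:
        if iv.chrom == chrom:
            mask[iv.start : iv.end] = True
    return mask


def simulate_methylome(
    genome: SyntheticGenome, spec: SyntheticSpec, pr_loss: bool = False
) -> Tuple[CoverageTrack, pd.DataFrame]:
    """Assign a methylation fraction to every CpG.

    Background CpGs get ``meth_background``, island CpGs ``meth_island``
    (raised to ``meth_island_pr_loss`` in PR-loss mode, emulating promoter
    hypermethylation upon receptor loss), and binding-site CpGs ``meth_site``
    — the site level overrides the island level.

    Returns the binned mean-fraction track (bins without CpG are missing)
    and a per-CpG table with columns chrom, pos, fraction.
    """
    rows = []
    data: Dict[str, np.ndarray] = {}
    island_level = spec.meth_island_pr_loss if pr_loss else spec.meth_island
    for chrom, length in genome.sizes.items():
        seq = genome.sequences[chrom]
        pos = cpg_positions(seq)
        frac = np.full(len(pos), spec.meth_background)
        in_island = _feature_mask(length, genome.islands, chrom)[pos]
        frac[in_island] = island_level
        in_site = _feature_mask(length, genome.sites, chrom)[pos]
        frac[in_site] = spec.meth_site
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos, "fraction": frac}))
        n_bins = math.ceil(length / spec.bin_size)
        sums = np.bincount(pos // spec.bin_size, weights=frac, minlength=n_bins)
        counts = np.bincount(pos // spec.bin_size, minlength=n_bins).astype(float)
        with np.errstate(invalid="ignore"):
            binned = sums / counts
        binned[counts == 0] = np.nan
        data[chrom] = binned
    track = CoverageTrack(bin_size=spec.bin_size, data=data, units="fraction")
    table = pd.concat(rows, ignore_index=True)
    return track, table


def simulate_medip_coverage(
    methylome: pd.DataFrame, spec: SyntheticSpec, sizes: ChromSizes
) -> Tuple[CoverageTrack, int]:
    """Simulate MeDIP fragment coverage from a per-CpG methylome.

    Each CpG independently contributes ``Poisson(depth * fraction)``
    fragments; a fragment covering a CpG starts uniformly within
    ``fragment_length`` upstream of it (clipped to the chromosome). The
    returned raw-count track holds the mean per-base fragment coverage per
    bin; enrichment is thus linear in methylated-CpG content, the simplest
    model with the correct monotonicity.
    """
    rng = spec.rng(_KEY_COVERAGE)
    data: Dict[str, np.ndarray] = {}
    library_size = 0
    frag = spec.fragment_length
    for chrom, length in sizes.items():
        sub = methylome[methylome["chrom"] == chrom]
        counts = rng.poisson(spec.depth * sub["fraction"].to_numpy())
        library_size += int(counts.sum())
        starts_at = np.repeat(sub["pos"].to_numpy(), counts)
        offsets = rng.integers(0, frag, size=len(starts_at))
        frag_starts = np.clip(starts_at - offsets, 0, max(0, length - frag))
        diff = np.zeros(length + 1)
        np.add.at(diff, frag_starts, 1.0)
        np.add.at(diff, np.minimum(frag_starts + frag, length), -1.0)
        per_base = np.cumsum(diff[:-1])
        n_bins = math.ceil(length / spec.bin_size)
        padded = np.zeros(n_bins * spec.bin_size)
        padded[:length] = per_base
        binned = padded.reshape(n_bins, spec.bin_size).sum(axis=1)
        widths = np.full(n_bins, spec.bin_size, dtype=float)
        widths[-1] = length - (n_bins - 1) * spec.bin_size
        data[chrom] = binned / widths
    track = CoverageTrack(bin_size=spec.bin_size, data=data, units="raw")
    return track, library_size


def simulate_clones(
    reference: str,
    cpg_fractions: Mapping[int, float],
    n_clones: int,
    conversion_rate: float = 1.0,
    seed: int = 0,
) -> List[str]:
    """Simulate bisulfite-converted clone sequences of a reference amplicon.

    Per clone, each CpG is methylated with its fraction; every unmethylated C
    (CpG or not) is converted C→T with ``conversion_rate``; methylated CpG Cs
    are never converted.
    """
    if not (0.0 <= conversion_rate <= 1.0):
        raise ValueError("conversion_rate must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_KEY_CLONES,)))
    ref = reference.upper()
    for p, f in cpg_fractions.items():
        if ref[p] != "C":
            raise ValueError(f"CpG offset {p} is not a C in the reference")
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"fraction at {p} outside [0, 1]")
    c_positions = [i for i, b in enumerate(ref) if b == "C"]
    clones = []
    for _ in range(n_clones):
        arr = list(ref)
        for i in c_positions:
            methylated = i in cpg_fractions and rng.random() < cpg_fractions[i]
            if not methylated and rng.random() < conversion_rate:
                arr[i] = "T"
        clones.append("".join(arr))
    return clones


def default_ct_effects() -> Dict[str, Dict[Tuple[str, str], float]]:
    """Planted expression folds relative to the (shC, vehicle) calibrator.

    The receptor gene (PGR) is knocked down 10-fold in shPR cells; the
    estrogen-receptor gene (ESR1) drops to half upon receptor loss; the
    estrogen-responsive gene (TFF1) is induced 6-fold by hormone in control
    cells but only residually (factor 0.2 on the induction) in knockdown
    cells.
    """
    return {
        "PGR": {("shPR", "vehicle"): 0.1, ("shPR", "E2"): 0.1},
        "ESR1": {("shPR", "vehicle"): 0.5, ("shPR", "E2"): 0.5},
        "TFF1": {("shC", "E2"): 6.0, ("shPR", "E2"): 6.0 * 0.2},
    }


def simulate_ct_table(
    effects: Optional[Mapping[str, Mapping[Tuple[str, str], float]]] = None,
    noise_sd: float = 0.2,
    seed: int = 0,
    samples: Sequence[str] = ("shC", "shPR"),
    conditions: Sequence[str] = ("vehicle", "E2"),
    n_replicates: int = 3,
    reference_gene: str = "GAPDH",
    baseline_ct: float = 25.0,
    reference_baseline_ct: float = 18.0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table with planted fold changes.

    ``Ct = baseline - log2(fold) + N(0, noise_sd)``; the reference gene's
    fold is fixed at 1 everywhere, and folds default to 1 for any
    (sample, condition) an effect map does not mention. The first
    sample/condition pair is the implicit calibrator.
    """
    if effects is None:
        effects = default_ct_effects()
    for gene, m in effects.items():
        if any(f <= 0 for f in m.values()):
            raise ValueError(f"folds must be positive (gene {gene!r})")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_KEY_CT,)))
    rows = []
    genes = list(effects) + [reference_gene]
    for sample in samples:
        for condition in conditions:
            for gene in genes:
                if gene == reference_gene:
                    base, fold = reference_baseline_ct, 1.0
                else:
                    base = baseline_ct
                    fold = effects[gene].get((sample, condition), 1.0)
                for rep in range(1, n_replicates + 1):
                    ct = base - math.log2(fold) + rng.normal(0.0, noise_sd)
                    rows.append(
                        {"sample": sample, "condition": condition, "gene": gene,
                         "replicate": rep, "ct": ct}
                    )
    return pd.DataFrame(rows)


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_dataset(spec: SyntheticSpec, outdir: str | Path, pr_loss: bool = False) -> Dict[str, str]:
    """Generate and write the full synthetic dataset; returns file paths.

    Writes genome.fa, chrom.sizes, islands.bed, sites.bed,
    methylation.bedGraph (per-bin mean fraction), medip_raw.bedGraph,
    ct_table.csv, clones.fa and manifest.json (spec echo plus library size).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(spec)
    meth_track, meth_table = simulate_methylome(genome, spec, pr_loss=pr_loss)
    medip, library_size = simulate_medip_coverage(meth_table, spec, genome.sizes)
    ct = simulate_ct_table(seed=spec.seed)

    # bisulfite clones of the first island (the promoter-like amplicon)
    island = genome.islands[0]
    ref = genome.sequences[island.chrom][island.start : island.end]
    sub = meth_table[
        (meth_table["chrom"] == island.chrom)
        & (meth_table["pos"] >= island.start)
        & (meth_table["pos"] < island.end)
    ]
    fractions = {int(p) - island.start: float(f) for p, f in zip(sub["pos"], sub["fraction"])}
    clones = simulate_clones(ref, fractions, n_clones=10, conversion_rate=0.99, seed=spec.seed)

    paths = {
        "genome": str(outdir / "genome.fa"),
        "chrom_sizes": str(outdir / "chrom.sizes"),
        "islands": str(outdir / "islands.bed"),
        "sites": str(outdir / "sites.bed"),
        "methylation": str(outdir / "methylation.bedGraph"),
        "medip_raw": str(outdir / "medip_raw.bedGraph"),
        "ct_table": str(outdir / "ct_table.csv"),
        "clones": str(outdir / "clones.fa"),
        "manifest": str(outdir / "manifest.json"),
    }
    write_fasta(genome.sequences, paths["genome"])
    write_chrom_sizes(genome.sizes, paths["chrom_sizes"])
    write_bed(genome.islands, paths["islands"])
    write_bed(genome.sites, paths["sites"])
    write_bedgraph(meth_track, genome.sizes, paths["methylation"])
    write_bedgraph(medip, genome.sizes, paths["medip_raw"])
    ct.to_csv(paths["ct_table"], index=False)
    write_fasta({f"clone_{i+1}": c for i, c in enumerate(clones)}, paths["clones"])
    manifest = {
        "spec": spec.to_dict(),
        "pr_loss": pr_loss,
        "library_size": library_size,
        "clone_amplicon": f"{island.chrom}:{island.start}-{island.end}",
        "files": {k: Path(v).name for k, v in paths.items()},
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return paths
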