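# Methods

This note documents the models, defaults and numerical choices behind
`methsite`: what each component computes, why the synthetic-data generator
looks the way it does, and what passing tests do and do not establish about
real data.

## Problem setting

Transcription-factor binding sites — here, progesterone-receptor binding
sites called from ChIP-seq — tend to be CpG-dense yet lowly methylated
relative to their flanking DNA, and methylation of CpGs inside or next to a
response element can impede receptor binding. The package implements the
computational side of that analysis: region-centered aggregation of
5-methylcytosine (5mC) immunoprecipitation signal and CpG density, a
permutation test of whether a region set is hypo- or hypermethylated
relative to random placement, IUPAC motif scanning with CpG annotation, peak
filtering, and the deterministic arithmetic of qPCR and bisulfite-clone
quantification.

## Coordinates and signal tracks

All coordinates are 0-based half-open (BED convention); printed browser
ranges are ingested as `start=left, end=right`. Chromosome names are matched
exactly; a `normalize_chrom` helper exists but is never applied implicitly.

Coverage tracks are binned per chromosome (default bin 50 bp, a typical
resolution for published heatmap matrices; configurable everywhere).
Missing data is an explicit NaN sentinel, never zero: a bin with no bedGraph
record and a bin with zero coverage are different observations, and every
mean in the package ignores missing bins rather than diluting with zeros.
Bin values from bedGraph input are coverage-weighted means of the records
overlapping the bin. RPM normalization multiplies by `1e6 / library_size`.

Region means are length-weighted over the bins a region overlaps. Region
matrices anchor at `floor((start+end)/2)` in center mode; each column is the
length-weighted mean over one `bin_size`-wide window, and windows extending
beyond the chromosome are missing. Scaled-body mode linearly partitions the
region into `body_bins` windows between the flank columns. Average profiles
are column means over non-missing entries (all-missing columns stay
missing). CpG density counts CG dinucleotides by the bin of their first
base, so a CG straddling a bin boundary is counted exactly once and the
genome-wide total is conserved.

## The shuffle null

The statistical core is a permutation test that preserves region sizes: each
replicate re-places every region independently and uniformly over all valid
start positions (chromosomes weighted by their number of valid starts), and
records the mean over regions of the per-region mean signal. The empirical
p-value uses the add-one convention,
`p = (1 + #{null means at least as extreme}) / (1 + n_replicates)`,
which is a valid p-value for a finite number of permutations and can never
be zero; its smallest attainable value at 1000 replicates is 1/1001.
"At least as extreme" means `null <= observed` for depletion,
`null >= observed` for enrichment; the two-sided p doubles the smaller tail,
capped at 1.

Defaults and their rationale:

* **1000 replicates** — the conventional size for an empirical null at
  which p ≈ 0.001 is resolvable.
* **Genome-wide placement, no exclusions** — the simplest well-defined null;
  same-chromosome placement and an exclusion BED (rejection sampling with a
  bounded number of retries) are flags.
* **Shuffled regions may overlap each other** — placements are independent;
  constraining them would couple the replicate's regions and complicate the
  null without changing its first-order behavior at the densities involved.
* **Mann-Whitney comparison** — per-region observed means against the
  pooled per-region null means (n vs n × replicates), one-sided in the
  direction under test; a replicate-means variant is available. The U test
  uses the exact distribution when both samples have ≤ 8 observations and no
  ties, otherwise the normal approximation with tie and continuity
  corrections.
* **Reproducibility** — replicate `r` draws from
  `SeedSequence(seed, spawn_key=(r,))`, so results are identical for a given
  seed and independent of evaluation order.

Per-region means inside the test are computed from per-base prefix sums of
the binned track (value and finite-mask cumulative sums), which gives exact
length-weighted means in O(1) per region and makes thousand-replicate runs
cheap.

## Motif scanning

Patterns are IUPAC strings; the default full response element
`RGNACANNNTGTNCY` and half site `TGTNCY` follow the steroid-receptor
consensus literature and are ordinary data the caller can replace. Matching
is case-insensitive, an `N` in the subject never matches (conservative), and
minus-strand hits are found by matching the reverse-complemented pattern on
the forward strand and reported in forward coordinates, so a palindromic
pattern yields a hit on each strand at the same start. CpG annotation counts
CG dinucleotides with at least one base inside the hit extended by
`neighbor_flank` (default 2 bp — "neighboring" CpGs immediately abutting a
half site still affect binding); counts 0 / 1 / ≥2 map to the sensitivity
classes none / single-CpG / multi-CpG. The scanner is implemented with
compiled character-class regular expressions inside a lookahead (so
overlapping hits are all reported); the test suite checks it against an
independent nested-loop matcher.

## Quantification arithmetic

* **Peak filtering** keeps `q_value < q_max` (strict, as thresholds on FDR
  are conventionally printed) AND `fold_enrichment >= min_fold` ("a 4-fold
  enrichment" read as at-least); both comparisons are flags. narrowPeak
  input stores `-log10(q)` in column 9 and is converted to the linear scale
  on read (`-1` meaning unavailable becomes q = 1); MACS2-style XLS tables
  are read by column name with their 1-based starts converted.
* **ΔΔCt**: `ΔCt = mean Ct(target) − mean Ct(reference)` per sample,
  `fold = efficiency^−(ΔCt_sample − ΔCt_calibrator)` with efficiency 2.0 by
  default (no efficiency correction, matching how relative values are
  usually reported; the parameter exists). Dispersion is the SD over
  replicate-wise folds, replicates paired between target and reference by
  replicate id — a choice, since "SD of three independent experiments"
  underdetermines the propagation. Induction folds use the same machinery
  with each sample's vehicle condition as its own calibrator.
* **Bisulfite clones** are assumed indel-free and pre-aligned. At each CpG
  offset, C → methylated, T → unmethylated, anything else → undetermined;
  per-position fractions use determined calls only. Conversion efficiency is
  the fraction of non-CpG reference cytosines read as T, per clone; a value
  near 0 flags a clone that escaped conversion (its "methylation" is an
  artifact).
* **t-test**: unpaired, two-tailed, pooled variance. Zero pooled variance
  with equal means returns (0, 1); with unequal means (±inf, 0).

## The synthetic-data generator

The generator emulates the statistical structure of the study's MeDIP-seq
data so the whole pipeline runs end to end from a seed. Defaults (the study
conditions for every simulation-based check):

| parameter | default | rationale |
|---|---|---|
| genome | 2 chromosomes × 1 Mb | minutes-scale tests, two chromosomes exercise cross-chromosome placement |
| background GC | 0.42 | mammalian-like |
| CpG islands | 20, 500–2000 bp, 5× CpG enrichment | island-like density (~0.22 CG/bp) |
| binding sites | 50 × 400 bp, 2× CpG enrichment | see below |
| methylation (background / island / site) | 0.7 / 0.1 / 0.2 | methylated genome, unmethylated islands, hypomethylated sites |
| receptor-loss island methylation | 0.8 | promoter hypermethylation upon receptor loss |
| MeDIP depth | 1 fragment per methylated CpG | ~60k fragments at default scale |
| fragment length | 300 bp | sonication fragment scale |

CpG-enriched regions are produced by an emitter that outputs a CG
dinucleotide with probability q and a background base otherwise; q is solved
by bisection so the *total* CG density (emitted CGs plus chance CGs between
single-base emissions) equals `enrichment × (gc/2)²`. Enrichment 1 therefore
reproduces plain background exactly. Islands and sites are placed by
rejection sampling so no two features overlap, and one concrete response
element (`GGAACAGAATGTTCT`, an instance of the full consensus) is planted at
each site's center.

The **site CpG enrichment of 2×** is forced by the structure being
emulated: sites must have *higher* CpG density but *lower* 5mC signal than
their flanks, and with MeDIP coverage linear in methylated-CpG content
(fraction × density) those two conditions require
`enrichment × meth_site / meth_background < 1`, i.e. < 3.5 at 0.2/0.7. A 2×
elevation is a realistic binding-site value and leaves a ~40% depletion in
expected methylated-CpG content.

MeDIP coverage draws `Poisson(depth × fraction)` fragments per CpG, each
starting uniformly within one fragment length upstream of its CpG, and
reports mean per-base fragment coverage per bin — linear in methylated-CpG
content, the simplest model with the correct monotonicity (no antibody
saturation, no GC amplification bias). Because fragments are 300 bp, the
coverage a bin receives reflects the methylated-CpG content of a
fragment-sized neighborhood, not of the 50 bp bin alone; proportionality
checks are therefore made at fragment-length resolution, and depletion at
400 bp sites is diluted by flanking signal (the detected effect at default
conditions is a ~35% reduction of the region mean, not the ~60% the raw
fraction contrast would suggest).

Bisulfite clone simulation methylates each CpG independently with its
fraction, then converts every unmethylated C (CpG or not) to T with the
conversion rate; methylated CpGs are never converted. Incomplete conversion
therefore biases calls toward methylation, exactly as in the real assay.
Ct tables are generated as `baseline − log2(fold) + N(0, noise_sd)` with the
reference gene's fold fixed at 1, conditions shC/shPR × vehicle/E2, three
replicates; planted folds are 0.1 (receptor knockdown), 0.5 (downstream
receptor loss), and a 6-fold hormone induction attenuated to 1.2-fold in
knockdown cells.

What the generator does **not** emulate: read-level sequencing error,
duplicate reads, mappability and GC bias, fragment-length variability,
copy-number structure, or biological replicate variance in MeDIP. Passing
the pipeline's tests shows the *computations* are correct under a clean
generative model with the right qualitative structure; it does not validate
the laboratory conclusions on real libraries.

## Calibration of the shuffle test

Under a no-effect configuration (all methylation levels equal, CpG
enrichments 1) the empirical p-value is uniform on its attainable grid. Two
subtleties, both verified by the test suite:

1. The observed region set must be exchangeable with the shuffled sets, so
   the calibration check uses randomly placed regions of the same sizes as
   the observed set. The planted sites themselves are *not* exactly null
   even at equal methylation levels, because the planted 15 bp element
   contains no CG and slightly lowers site CpG density — a real, if tiny,
   depletion.
2. The per-run coverage must be redrawn, since the p-value conditions on the
   track.

Power at the default conditions (50 sites, depletion, 1000 replicates) is
effectively complete: the planted hypomethylation is detected at p ≤ 0.01 in
at least 95 of 100 seeds, in practice at the attainable minimum 1/1001.

## Degenerate inputs and tie-breaking

Empty region sets, all-missing signal over the observed regions, empty
motif-pattern strings, non-positive library sizes or thresholds, and Ct
tables with duplicate (sample, condition, gene, replicate) keys are
rejected with named errors rather than propagated as NaN. Regions whose
signal is entirely missing are dropped from the set mean (observed and null
computed identically). A shuffled placement that cannot avoid the exclusion
list within the retry budget raises rather than silently relaxing the
constraint. Hits are ordered by (start, strand), duplicated hits from
overlapping scan regions are removed by (chrom, start, strand, pattern).

## Known limitations

* The shuffle null is not GC- or chromatin-matched; if real binding sites
  preferentially occupy CpG-dense DNA, the genome-wide null conflates
  sequence composition with methylation state (the CpG-density profile is
  the companion analysis that makes this visible).
* Linear-scan interval arithmetic is O(n·m) against exclusion lists —
  adequate for hundreds of regions, not for genome-scale annotation sets.
* The Mann-Whitney comparison against pooled shuffled means treats the
  pooled sample as i.i.d., ignoring the replicate structure; with 50 × 1000
  pooled values its p-values are far smaller than the empirical p and should
  be read as a descriptive contrast, not an independent test.
* bigWig I/O is not implemented; tracks move as bedGraph text.
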