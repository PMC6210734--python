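#!/usr/bin/env python
"""Filter a peak list at the FDR and fold-enrichment thresholds.

Builds a toy peak table over the synthetic binding sites — true sites get
strong statistics, decoy intervals get weak ones — applies the
q < 1e-6 AND fold >= 4 filter, and writes the surviving peaks in narrowPeak
format under results/peaks/.
"""

import argparse
from pathlib import Path

import numpy as np

from methsite.intervals import GenomicInterval
from methsite.quantify import PeakRecord, filter_peaks, write_narrowpeak
from methsite.shuffle import shuffle_intervals
from methsite.simulate import SyntheticSpec, generate_genome


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/peaks"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    spec = SyntheticSpec(seed=args.seed)
    genome = generate_genome(spec)
    rng = np.random.default_rng(args.seed)

    peaks = []
    for iv in genome.sites:  # true sites: strong enrichment, tiny q
        peaks.append(PeakRecord(
            interval=GenomicInterval(iv.chrom, iv.start, iv.end, name=iv.name),
            summit_offset=iv.length // 2,
            fold_enrichment=float(rng.uniform(4, 12)),
            q_value=float(10 ** -rng.uniform(6.5, 12)),
        ))
    decoys = shuffle_intervals(genome.sites, genome.sizes, seed=args.seed + 1)
    for i, iv in enumerate(decoys):  # decoys: weak statistics
        peaks.append(PeakRecord(
            interval=GenomicInterval(iv.chrom, iv.start, iv.end, name=f"decoy_{i}"),
            summit_offset=iv.length // 2,
            fold_enrichment=float(rng.uniform(0.5, 5)),
            q_value=float(10 ** -rng.uniform(0, 6.5)),
        ))

    write_narrowpeak(peaks, args.outdir / "all_peaks.narrowPeak")
    kept = filter_peaks(peaks)
    write_narrowpeak(kept, args.outdir / "filtered_peaks.narrowPeak")
    n_true = sum(1 for p in kept if not p.interval.name.startswith("decoy"))
    print(f"{len(kept)}/{len(peaks)} peaks pass q<1e-6 and fold>=4 "
          f"({n_true} true sites, {len(kept) - n_true} decoys)")


if __name__ == "__main__":
    main()
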