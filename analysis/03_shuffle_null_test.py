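#!/usr/bin/env python
"""Test binding-site hypomethylation against the size-preserving shuffle null.

Runs the full pipeline at the default conditions and asks whether the mean
5mC signal over the 50 binding sites is lower than expected for 50 regions
of the same sizes placed at random (1000 shuffles), reporting the empirical
p-value and the Mann-Whitney comparison. Writes results/shuffle/result.json.
"""

import argparse
from pathlib import Path

import numpy as np

from methsite.shuffle import empirical_null_test
from methsite.simulate import (
    SyntheticSpec,
    generate_genome,
    simulate_medip_coverage,
    simulate_methylome,
)
from methsite.tracks import rpm_normalize


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-replicates", type=int, default=1000)
    ap.add_argument("--outdir", type=Path, default=Path("results/shuffle"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    spec = SyntheticSpec(seed=args.seed)
    genome = generate_genome(spec)
    _, meth_table = simulate_methylome(genome, spec)
    medip, lib = simulate_medip_coverage(meth_table, spec, genome.sizes)
    rpm = rpm_normalize(medip, lib)

    result = empirical_null_test(
        rpm, genome.sites, genome.sizes,
        n_replicates=args.n_replicates, direction="depletion", seed=args.seed,
    )
    result.to_json(args.outdir / "result.json")

    null_mean = float(np.nanmean(result.null_means))
    print(f"observed mean 5mC over {result.n_regions} sites: {result.observed_mean:.4g} RPM")
    print(f"shuffle-null mean of means ({result.n_replicates} replicates): {null_mean:.4g} RPM")
    print(f"empirical p (depletion, add-one convention): {result.empirical_p:.4g}")
    print(f"Mann-Whitney U={result.mw_u:.4g}, p={result.mw_p:.3g} "
          f"(per-site means vs pooled shuffled means)")


if __name__ == "__main__":
    main()
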