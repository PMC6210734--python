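import numpy as np
import pytest
from hypothesis import settings

from methsite.simulate import SyntheticSpec

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def small_spec():
    """Reduced genome for fast end-to-end tests (same structure as defaults)."""
    return SyntheticSpec(
        chrom_lengths={"chr1": 120_000, "chr2": 80_000},
        n_islands=4,
        island_length_range=(300, 800),
        n_sites=10,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_genome(small_spec):
    from methsite.simulate import generate_genome

    return generate_genome(small_spec)


@pytest.fixture(scope="session")
def small_pipeline(small_spec, small_genome):
    """Genome + methylome + RPM-normalized MeDIP coverage at the small scale."""
    from methsite.simulate import simulate_medip_coverage, simulate_methylome
    from methsite.tracks import rpm_normalize

    meth_track, meth_table = simulate_methylome(small_genome, small_spec)
    medip, lib = simulate_medip_coverage(meth_table, small_spec, small_genome.sizes)
    return {
        "spec": small_spec,
        "genome": small_genome,
        "meth_track": meth_track,
        "meth_table": meth_table,
        "medip": medip,
        "library_size": lib,
        "rpm": rpm_normalize(medip, lib),
    }
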