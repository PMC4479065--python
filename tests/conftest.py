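import numpy as np
import pytest
from hypothesis import settings

import breedld as bl

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_pop():
    """One random-mating population with realistic LD, reused across tests."""
    cfg = bl.SimConfig(n_chromosomes=3, chrom_length_mb=10, n_markers_per_chrom=120,
                       ne_trajectory=[(200, 80)], sample_sizes={"P": 60}, seed=101)
    return bl.simulate(cfg)["P"]


@pytest.fixture(scope="session")
def small_geno(small_pop):
    """Genotypes of ``small_pop`` with 3% missing entries."""
    return bl.to_genotypes(small_pop, missing_rate=0.03, seed=7)


@pytest.fixture()
def toy_triplet():
    """Tiny handcrafted genotype/map/sample triplet for I/O round trips."""
    rng = np.random.default_rng(42)
    doses = rng.integers(0, 3, size=(5, 8)).astype(np.int8)
    doses[1, 2] = bl.MISSING
    doses[4, 6] = bl.MISSING
    markers = bl.MarkerMap(
        chrom=np.array(["1", "1", "1", "2", "2", "2", "3", "3"]),
        pos=np.array([10_000, 55_000, 130_000, 20_000, 90_000, 240_000,
                      15_000, 75_000]),
        name=np.array([f"m{k}" for k in range(8)]))
    samples = bl.SampleTable(np.array([f"s{i}" for i in range(5)]),
                             np.array(["POP1", "POP1", "POP1", "POP2", "POP2"]))
    geno = bl.GenotypeMatrix(doses, samples,
                             np.array(list("ACGTACGT")), np.array(list("GTACGTAC")))
    return geno, markers, samples
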