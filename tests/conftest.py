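import numpy as np
import pytest

from imputefirst.formats import Contig, GeneticMap
from imputefirst.simulate import SimConfig, simulate_donor, simulate_panel, simulate_reads


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A 30 kb cohort small enough for brute-force cross-checks."""
    return SimConfig(
        genome_length=30_000, n_sites=80, n_haplotypes=8, coverage=5.0, seed=7
    )


@pytest.fixture(scope="session")
def small_world(small_cfg):
    """(reference, panel, truth, reads) for the small cohort."""
    ref, panel = simulate_panel(small_cfg)
    truth = simulate_donor(ref, panel, small_cfg)
    reads = simulate_reads(truth, small_cfg)
    return ref, panel, truth, reads


@pytest.fixture(scope="session")
def flat_map(small_cfg) -> GeneticMap:
    return GeneticMap.uniform(small_cfg.genome_length)


def random_contig(rng: np.random.Generator, length: int, name: str = "chrT") -> Contig:
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
    return Contig(name, seq)
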