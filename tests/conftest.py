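import numpy as np
import pytest

from cellqtl.simulate import (LocusSpec, SimConfig, build_truth,
                              simulate_genotypes)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A reduced cohort for unit tests: 2 loci, 200 subjects, 3 cell types."""
    return SimConfig(
        n_subjects=200, variants_per_locus=12,
        loci=(LocusSpec("shared_causal"), LocusSpec("null")),
        cell_types=("GLU", "Oli", "Mic"), cells_per_subject_per_type=10,
        n_background_genes=10, seed=11)


@pytest.fixture(scope="session")
def small_genotypes(small_config):
    return simulate_genotypes(small_config, stream=1)


@pytest.fixture(scope="session")
def small_truth(small_config, small_genotypes):
    return build_truth(small_config, small_genotypes)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
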