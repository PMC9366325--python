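import numpy as np
import pytest

from senemeth.simulate import SyntheticConfig, generate_genome, build_truth, write_fixture_set
from senemeth.io import read_cx_report


def small_synthetic_config(seed: int = 7) -> SyntheticConfig:
    """Desk-scale config: 100 kb over 2 chromosomes, sparse features."""
    return SyntheticConfig(
        genome_length=100_000,
        n_chromosomes=2,
        n_genes=20,
        n_tes=10,
        motif_plantings={
            "W-box": {"promoter": 6, "gene": 6, "TE": 6, "intergenic": 6},
            "A-box": {"promoter": 2, "gene": 2, "TE": 2, "intergenic": 2},
            "C-box": {"promoter": 2, "gene": 2, "TE": 2, "intergenic": 2},
            "G-box": {"promoter": 2, "gene": 2, "TE": 2, "intergenic": 2},
        },
        n_dmr_hypo_cg=4,
        n_dmr_hyper_late=4,
        n_dml_hypo_cg=8,
        n_dml_hyper_late=8,
        rng_seed=seed,
    )


@pytest.fixture(scope="session")
def small_config():
    return small_synthetic_config()


@pytest.fixture(scope="session")
def small_genome(small_config):
    return generate_genome(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config, small_genome):
    genome, features, _registry = small_genome
    return build_truth(genome, features, small_config)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_config):
    """Full 12-sample fixture set written once per session."""
    d = tmp_path_factory.mktemp("fixture")
    write_fixture_set(small_config, d)
    return d


@pytest.fixture(scope="session")
def fixture_samples(fixture_dir, small_config):
    samples = []
    for stage in small_config.stages:
        for rep in range(1, small_config.n_replicates + 1):
            samples.append(
                read_cx_report(
                    fixture_dir / f"{stage}_rep{rep}.CX_report.txt",
                    stage=stage,
                    replicate=str(rep),
                )
            )
    return samples


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
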