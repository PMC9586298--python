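import pytest

from cocomet.simulate import SimulationConfig, generate_study


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study: 200 features, 3 replicates, 60 genes/genome."""
    return SimulationConfig(
        n_features=200,
        n_kec_features=6,
        n_threeway_only=5,
        n_pairwise_only=12,
        n_replicates=3,
        n_media_replicates=3,
        n_genes_per_genome=60,
        n_bgc_per_genome=3,
        bgc_size=5,
        library_size=200_000,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config, seed=11)


@pytest.fixture(scope="session")
def zero_noise_study(small_config):
    import dataclasses

    cfg = dataclasses.replace(small_config, noise_sigma=0.0)
    return generate_study(cfg, seed=11)
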