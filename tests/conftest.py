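import pytest

from trackforest import SimConfig, build_forest, simulate_forest


@pytest.fixture(scope="session")
def small_config():
    """A fast but structurally rich recording: divisions, both death modes,
    resistant lineages, heritable traits."""
    return SimConfig(
        duration_h=40.0,
        frame_interval_h=0.5,
        field_width=400.0,
        field_height=300.0,
        n_roots=12,
        division_mean_h=15.0,
        division_sd_h=2.0,
        heritability=0.5,
        death_hazard_apoptotic=0.01,
        death_hazard_necrotic=0.005,
        resistant_fraction=0.3,
        speed_mult_sd=0.3,
        noise_sd=0.5,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_forest(small_config, 42)


@pytest.fixture(scope="session")
def small_forest(small_dataset):
    return build_forest(small_dataset)
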