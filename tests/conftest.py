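import pytest

from juriflux.synthetic import SyntheticConfig, StratumSpec, \
    generate_landscape, generate_footprints


@pytest.fixture(scope="session")
def default_landscape():
    """One default synthetic jurisdiction shared across tests."""
    return generate_landscape(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def default_footprints(default_landscape):
    return generate_footprints(default_landscape, n_per_stratum=80,
                               noise_cv=0.10, seed=11)


def single_stratum_config(**overrides) -> SyntheticConfig:
    """Minimal one-stratum jurisdiction used for arithmetic checks."""
    base = dict(
        shape=(100, 100),
        tp=10,
        seed=0,
        strata=[StratumSpec("only", "primary", "lowland", "low_fertility",
                            150.0, 1.0)],
        loss_fracs={"agriculture": 0.01},
        n_roads=0,
        n_concession_blocks=0,
        gain_frac_yr=0.0,
        asl_frac_yr=0.0,
    )
    base.update(overrides)
    return SyntheticConfig(**base)
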