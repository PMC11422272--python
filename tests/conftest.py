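import pytest

from fishmetals import core_data, exposure_risk


@pytest.fixture(scope="session")
def fixtures():
    return core_data.load_fixtures()


@pytest.fixture(scope="session")
def exposure_inputs(fixtures):
    """(constants, strata, scenarios, profiles, days_per_month)."""
    return exposure_risk.load_exposure_inputs(fixtures.tox)


@pytest.fixture(scope="session")
def grand_means_ww(fixtures):
    """Muscle grand means (mean of the 11 per-dam means), converted to ww."""
    from fishmetals import basis_conversion

    m = fixtures.tox["moisture_fraction"]["muscle"]
    return {
        metal: basis_conversion.to_wet(
            core_data.grand_mean(fixtures.summaries, "muscle", metal), m
        )
        for metal in ("Cd", "Cu", "Zn")
    }


@pytest.fixture(scope="session")
def small_specimens():
    """A small deterministic synthetic specimen set shared across tests."""
    from fishmetals import synthetic_data

    return synthetic_data.generate(synthetic_data.GeneratorConfig(seed=7))
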