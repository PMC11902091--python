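import pytest

from metabocurate import simulate


@pytest.fixture(scope="session")
def fixtures():
    """Packaged in-study tables plus the miniature library/graph."""
    return simulate.packaged_fixtures()


@pytest.fixture(scope="session")
def default_study():
    return simulate.simulate_study(simulate.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def planted_study():
    cfg = simulate.SimulationConfig(
        seed=7,
        n_blank_violations=3,
        n_low_intensity=2,
        n_unidentified=2,
        n_low_prevalence=2,
        n_duplicate_pairs=2,
    )
    return simulate.simulate_study(cfg)
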