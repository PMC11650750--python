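import pytest

from chloropop import synthetic as syn


@pytest.fixture(scope="session")
def ref_profiles_panel():
    """Default 11-gene reference set, 6 profiles, 10-site diagnostic panel."""
    return syn.make_reference_and_profiles(seed=11, outgroup_divergence=30)


@pytest.fixture(scope="session")
def references(ref_profiles_panel):
    return ref_profiles_panel[0]


@pytest.fixture(scope="session")
def profile_defs(ref_profiles_panel):
    return ref_profiles_panel[1]


@pytest.fixture(scope="session")
def panel(ref_profiles_panel):
    return ref_profiles_panel[2]


@pytest.fixture(scope="session")
def layout():
    return syn.example_layout(seed=7)


@pytest.fixture(scope="session")
def population(layout, profile_defs):
    cfg = syn.SimulationConfig(seed=7)
    return syn.simulate_population(layout, profile_defs, cfg)
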