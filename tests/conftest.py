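import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_panel():
    """The default 30-species synthetic panel, generated once per session."""
    from tegc.synthetic import PanelSpec, generate_panel

    return generate_panel(PanelSpec())


@pytest.fixture(scope="session")
def default_profiles(default_panel):
    from tegc.te_library import species_gc_te

    return [
        species_gc_te(lib, species_id=truth.species_id)
        for lib, truth in zip(default_panel.libraries, default_panel.species)
    ]
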