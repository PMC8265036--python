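import pytest

from fibersync.synth import default_study


@pytest.fixture(scope="session")
def study():
    """The default synthetic study (compendium-proportioned, seed 7)."""
    return default_study(seed=7)
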