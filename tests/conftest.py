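import pytest
from hypothesis import settings

from golgiscreen.synth import default_config, simulate_bundle, write_bundle

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic bundle (seed 1): 3 shared planted candidates + decoys."""
    return simulate_bundle(default_config(1))


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    """The same bundle written to disk, for file-based pipeline tests."""
    out = tmp_path_factory.mktemp("bundle")
    paths = write_bundle(bundle, out)
    return paths
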