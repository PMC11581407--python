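import pytest

from listenrich import SyntheticTruth, generate_universe, write_bundle


@pytest.fixture(scope="session")
def truth1():
    return SyntheticTruth(seed=1)


@pytest.fixture(scope="session")
def universe1(truth1):
    """Default synthetic transcript universe (10,903 features, seed 1)."""
    return generate_universe(truth1)


@pytest.fixture(scope="session")
def bundle1(truth1, tmp_path_factory):
    """Full synthetic file bundle written once per session."""
    outdir = tmp_path_factory.mktemp("bundle1")
    paths = write_bundle(truth1, outdir)
    return outdir, paths
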