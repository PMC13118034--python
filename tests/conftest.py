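import pytest
from hypothesis import settings

from gemrefinery import synth
from gemrefinery.model import classify_all

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture():
    """Default planted fixture, classified; treat as read-only."""
    fx = synth.build_fixture()
    classify_all(fx.model)
    return fx


@pytest.fixture()
def model(fixture):
    """Fresh mutable copy of the fixture model."""
    return fixture.model.copy()


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Fixture files on disk (SBML + all tables + manifest)."""
    outdir = tmp_path_factory.mktemp("fixture")
    synth.generate(synth.FixtureSpec(seed=1), outdir)
    return outdir
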