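import pytest

from carcwoe.dataset import load_fixture
from carcwoe.pipeline import load_default_kb, run_pipeline


@pytest.fixture(scope="session")
def kb():
    return load_default_kb()


@pytest.fixture(scope="session")
def fixture_ds(kb):
    return load_fixture(kb.vocab)


@pytest.fixture(scope="session")
def result(fixture_ds, kb):
    """Full pipeline run on the packaged 289-compound reference dataset."""
    return run_pipeline(fixture_ds, kb)
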