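import numpy as np
import pytest

from ionprior.toypanel import build_toy_panel


@pytest.fixture(scope="session")
def toy_panel():
    """(transcripts, panel_by_symbol, reference) for the packaged toy genes."""
    return build_toy_panel()


@pytest.fixture(scope="session")
def transcripts(toy_panel):
    return toy_panel[0]


@pytest.fixture(scope="session")
def panel(toy_panel):
    """Panel as the list the pipeline functions take."""
    return list(toy_panel[1].values())


@pytest.fixture(scope="session")
def reference(toy_panel):
    return toy_panel[2]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
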