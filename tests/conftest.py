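import matplotlib

matplotlib.use("Agg")

import pytest

from gsanet.fixtures import make_caption_like_case, make_toy_case


@pytest.fixture(scope="session")
def caption_case():
    """Hand-built worked example: SPL(A,B)=3, SPL(C,D)=4, cross-pairs >= 5."""
    return make_caption_like_case()


@pytest.fixture(scope="session")
def toy_case():
    """One deterministic planted-module case shared by read-only tests."""
    return make_toy_case(seed=7)


@pytest.fixture
def bundle_dir(tmp_path, toy_case):
    """The toy case written to disk in the tool's input dialects."""
    from gsanet.fixtures import write_case

    write_case(toy_case, tmp_path / "bundle")
    return tmp_path / "bundle"
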