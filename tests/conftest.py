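import pytest

from entorflp import PRESETS, amplify_groups, make_reference_panel


@pytest.fixture(scope="session")
def reference_panel():
    """The shipped synthetic four-group panel (templates with flanks)."""
    return make_reference_panel()


@pytest.fixture(scope="session")
def full_amplicons(reference_panel):
    """Groups of full-length (1,075 bp) ITS-like amplicons."""
    fwd, rev = PRESETS["ITS-full"]
    return amplify_groups(reference_panel, fwd, rev)


@pytest.fixture(scope="session")
def short_amplicons(reference_panel):
    """Groups of 214-bp short amplicons spanning the MslI site."""
    fwd, rev = PRESETS["ITS2-short"]
    return amplify_groups(reference_panel, fwd, rev)
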