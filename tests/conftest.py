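import pytest

from cobakit.simulate import make_catalog


@pytest.fixture(scope="session")
def toy_catalog():
    """Synthetic catalog: 3 markers per (module, branch) slot, 15 required
    markers per branch (9 shared + 6 branch-exclusive)."""
    return make_catalog(n_per_module=3)
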