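import pytest

from mtplex import build_mini_reference, build_tree, load_panel


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def tree(panel):
    return build_tree(panel)


@pytest.fixture(scope="session")
def miniref(panel):
    return build_mini_reference(panel, seed=1)


@pytest.fixture(scope="session")
def callable_nodes(tree):
    """Every emittable haplogroup label (nodes owning a panel site)."""
    return [n for n in tree.parent if tree.site_of[n] is not None]
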