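import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mitotrack import (
    HaplogroupNode,
    HaplogroupTree,
    SynthSpec,
    generate_toy_tree,
    packaged_reference,
)
from mitotrack.variants import parse_variant_tokens


@pytest.fixture(scope="session")
def reference():
    return packaged_reference()


def _node(name, parent, tokens=""):
    return HaplogroupNode(name, parent, parse_variant_tokens(tokens))


@pytest.fixture(scope="session")
def toy_tree():
    """Hand-built nomenclature-style tree used across the suite.

    Includes a back-mutation branch (A1a), a natural-sort sibling set
    (H1/H2/H10), a control-region-ambiguous sibling pair (D4a/D4b differ
    only at the coding positions 3010/3012), and a distant clade E for
    chimera tests. All positions avoid the default hotspot mask.
    """
    nodes = [
        _node("mt-MRCA", None),
        _node("A", "mt-MRCA", "73 263"),
        _node("A1", "A", "1000"),
        _node("A1a", "A1", "73! 5000"),
        _node("B", "mt-MRCA", "16311"),
        _node("B1", "B", "4500"),
        _node("D", "mt-MRCA", "16223 16093"),
        _node("D4", "D", "16129"),
        _node("D4a", "D4", "3010"),
        _node("D4b", "D4", "3012"),
        _node("E", "mt-MRCA", "146"),
        _node("E1", "E", "195"),
        _node("H", "mt-MRCA", "2706"),
        _node("H1", "H", "3080"),
        _node("H2", "H", "1438"),
        _node("H10", "H", "14766"),
    ]
    return HaplogroupTree(nodes)


@pytest.fixture(scope="session")
def seeded_tree_50(reference):
    """Seeded 50-haplogroup random tree with unique cumulative profiles."""
    spec = SynthSpec(n_haplogroups=50, seed=11)
    tree, truth = generate_toy_tree(spec, reference)
    return tree, truth, spec
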