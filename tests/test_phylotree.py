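import numpy as np
import pytest

from mitotrack import (
    HaplogroupNode,
    HaplogroupTree,
    load_tree,
    natural_key,
    reference_sequence,
    save_tree,
)
from mitotrack.phylotree import TreeError, apply_variants, haplogroup_fragment
from mitotrack.variants import TRANSITION_PARTNER, format_variant, parse_variant_tokens


def tokens(variants):
    return sorted(format_variant(v) for v in variants)


# -- structure and loading ---------------------------------------------


def test_load_minimal_tree(tmp_path):
    path = tmp_path / "tree.tsv"
    path.write_text(
        "haplogroup\tparent\tvariants\nroot\t\t\nA\troot\t73\nA1\tA\t152\n"
    )
    tree = load_tree(path)
    assert len(tree) == 3 and tree.root == "root"
    assert tokens(tree.cumulative_profile("A1")) == ["152", "73"]


def test_load_rejects_self_parent(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("haplogroup\tparent\tvariants\nroot\t\t\nX\tX\t73\n")
    with pytest.raises(TreeError, match="own parent"):
        load_tree(path)


@pytest.mark.parametrize(
    "rows,message",
    [
        ("root\t\t\nroot\t\t\n", "duplicate"),
        ("root\t\t\nA\tnope\t73\n", "unknown parent"),
        ("root\t\t\nA\troot\tzzz\n", "malformed"),
        ("A\tB\t73\nB\tA\t152\n", "root"),
    ],
)
def test_load_rejects_malformed_trees(tmp_path, rows, message):
    path = tmp_path / "bad.tsv"
    path.write_text("haplogroup\tparent\tvariants\n" + rows)
    with pytest.raises(TreeError, match=message):
        load_tree(path)


def test_tree_tsv_round_trip(tmp_path, toy_tree):
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    save_tree(toy_tree, p1)
    reloaded = load_tree(p1)
    save_tree(reloaded, p2)
    assert p1.read_text() == p2.read_text()
    assert set(reloaded.nodes) == set(toy_tree.nodes)
    for name in toy_tree.nodes:
        assert reloaded.cumulative_profile(name) == toy_tree.cumulative_profile(name)


# -- cumulative profiles -----------------------------------------------


def test_root_profile_empty(toy_tree):
    assert toy_tree.cumulative_profile("mt-MRCA") == frozenset()


def test_back_mutation_cancels_ancestral_variant(toy_tree):
    # A carries 73 263; A1 adds 1000; A1a has 73! 5000
    assert tokens(toy_tree.cumulative_profile("A1")) == ["1000", "263", "73"]
    assert tokens(toy_tree.cumulative_profile("A1a")) == ["1000", "263", "5000"]


def test_same_position_overwrite():
    tree = HaplogroupTree(
        [
            HaplogroupNode("r", None, []),
            HaplogroupNode("x", "r", parse_variant_tokens("16189")),
            HaplogroupNode("y", "x", parse_variant_tokens("16189T")),
        ]
    )
    assert tokens(tree.cumulative_profile("y")) == ["16189T"]


def test_child_profile_differs_by_branch_after_cancellation(seeded_tree_50):
    tree, _, _ = seeded_tree_50
    for name, node in tree.nodes.items():
        if node.parent is None:
            continue
        parent = set(tree.cumulative_profile(node.parent))
        child = set(tree.cumulative_profile(name))
        expected = dict((v.site_key, v) for v in parent)
        for v in node.branch_variants:
            if v.back_mutation:
                expected.pop(v.site_key, None)
            else:
                expected[v.site_key] = v
        assert child == set(expected.values())


def test_unknown_haplogroup_raises(toy_tree):
    with pytest.raises(TreeError, match="unknown"):
        toy_tree.cumulative_profile("Z9")


# -- mrca ---------------------------------------------------------------


def test_mrca_examples(toy_tree):
    assert toy_tree.mrca(["D4a"]) == "D4a"
    assert toy_tree.mrca(["H1", "H10"]) == "H"
    assert toy_tree.mrca(["D4a", "mt-MRCA"]) == "mt-MRCA"
    assert toy_tree.mrca(["A1a", "B1"]) == "mt-MRCA"
    assert toy_tree.mrca(["D4", "D4a", "D4b"]) == "D4"
    with pytest.raises(TreeError):
        toy_tree.mrca([])


def test_mrca_set_properties(seeded_tree_50):
    """mrca is commutative/associative and ancestral to all inputs."""
    tree, _, _ = seeded_tree_50
    rng = np.random.default_rng(3)
    names = sorted(tree.nodes)
    for _ in range(25):
        group = list(rng.choice(names, size=3, replace=True))
        m = tree.mrca(group)
        assert tree.mrca(group[::-1]) == m
        assert tree.mrca([tree.mrca(group[:2]), group[2]]) == m
        for g in group:
            assert tree.is_ancestor(m, g)


# -- sub-haplogroups and discrimination --------------------------------


def test_sub_haplogroups_natural_order(toy_tree):
    assert toy_tree.sub_haplogroups("H", 1) == ["H1", "H2", "H10"]
    assert toy_tree.sub_haplogroups("H1", 1) == []
    assert toy_tree.sub_haplogroups("D", 2) == ["D4a", "D4b"]


def test_sub_haplogroups_structural_skip():
    nodes = [
        HaplogroupNode("r", None, []),
        HaplogroupNode("X", "r", parse_variant_tokens("73")),
        HaplogroupNode("X1'2", "X", []),  # pass-through structural node
        HaplogroupNode("X1", "X1'2", parse_variant_tokens("152")),
        HaplogroupNode("X2", "X1'2", parse_variant_tokens("263")),
    ]
    tree = HaplogroupTree(nodes)
    assert tree.sub_haplogroups("X", 1) == ["X1'2"]
    assert tree.sub_haplogroups("X", 1, skip_structural=True) == ["X1", "X2"]


def test_natural_key_orders_numeric_segments():
    names = ["H10", "H2", "H1", "H106", "H1a2", "H1a10"]
    assert sorted(names, key=natural_key) == ["H1", "H1a2", "H1a10", "H2", "H10", "H106"]


def test_discriminating_variants(toy_tree):
    disc = toy_tree.discriminating_variants({"D4a", "D4b"})
    assert {format_variant(v): set(c) for v, c in disc.items()} == {
        "3010": {"D4a"},
        "3012": {"D4b"},
    }
    # parent/child differ by the child's branch variant
    disc = toy_tree.discriminating_variants({"A1", "A1a"})
    assert {format_variant(v): set(c) for v, c in disc.items()} == {
        "73": {"A1"},
        "5000": {"A1a"},
    }
    with pytest.raises(TreeError):
        toy_tree.discriminating_variants({"D4a"})


def test_identical_profiles_have_no_discriminators():
    nodes = [
        HaplogroupNode("r", None, []),
        HaplogroupNode("p", "r", parse_variant_tokens("73")),
        HaplogroupNode("q", "p", []),  # same profile as p
    ]
    tree = HaplogroupTree(nodes)
    assert tree.discriminating_variants({"p", "q"}) == {}


# -- sequence reconstruction -------------------------------------------


def test_reference_sequence_root_identity(toy_tree, reference):
    assert reference_sequence(toy_tree, "mt-MRCA", reference) == reference


def test_transition_applied_at_263(toy_tree, reference):
    seq = reference_sequence(toy_tree, "A", reference)
    assert seq[262] == TRANSITION_PARTNER[reference[262]]
    assert seq[72] == TRANSITION_PARTNER[reference[72]]
    assert len(seq) == len(reference)


def test_deletion_shortens_sequence(reference):
    tree = HaplogroupTree(
        [
            HaplogroupNode("r", None, []),
            HaplogroupNode("x", "r", parse_variant_tokens("249d")),
        ]
    )
    assert len(reference_sequence(tree, "x", reference)) == 16568


def test_insertion_lengthens_sequence(reference):
    out = apply_variants(reference, parse_variant_tokens("1000.1A 1000.2C"))
    assert len(out) == len(reference) + 2
    assert out[999:1003].startswith(reference[999] + "AC")


def test_haplogroup_fragment_matches_full_sequence(toy_tree, reference):
    full = reference_sequence(toy_tree, "D4a", reference)
    frag = haplogroup_fragment(toy_tree, "D4a", reference, (2900, 3100))
    assert frag == full[2899:3100]
    assert frag[3010 - 2900] != reference[3010 - 1]


def test_transition_on_placeholder_warns(reference):
    warnings = []
    apply_variants(reference, parse_variant_tokens("3107"), warnings=warnings)
    assert warnings and "3107" in warnings[0]
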