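import pytest

from mitotrack import (
    Fragment,
    HaplotypeDB,
    SampleProfile,
    classify,
    narrow_candidates,
    propose_targets,
    read_panel,
    simulate_all,
    simulate_tracking,
    start_tracking,
    tile_panel,
    track_update,
)
from mitotrack.phylotree import haplogroup_fragment
from mitotrack.tracking import (
    DEFAULT_CR_AMPLICONS,
    AmpliconDef,
    TrackingError,
    amplicon_fragments,
    save_panel,
)
from mitotrack.variants import format_variant


def cr_sample(tree, hg):
    tokens = " ".join(
        format_variant(v)
        for v in tree.cumulative_profile(hg)
        if v.position >= 16024 or v.position <= 576
    )
    return SampleProfile.from_tokens(hg, tokens, [(16024, 16569), (1, 576)])


# -- narrowing ----------------------------------------------------------


def test_narrow_single_candidate(toy_tree):
    result = classify(
        SampleProfile.from_tokens("s", "16311 4500", [(1, 16569)]), toy_tree
    )
    names, mrca = narrow_candidates(result, toy_tree)
    assert names == ["B1"] and mrca == "B1"


def test_narrow_prefers_scored_candidates(toy_tree):
    db = HaplotypeDB(H={"D4a": 5}, He={("D4a", "7500"): 3})
    sample = SampleProfile.from_tokens(
        "s", "16223 16093 16129 7500", [(16024, 16569), (1, 576), (7400, 7600)]
    )
    result = classify(sample, toy_tree, db)
    assert len(result.rank_group_1()) == 3  # D4, D4a, D4b tie
    names, mrca = narrow_candidates(result, toy_tree)
    assert names == ["D4a"]  # the only scored candidate
    assert mrca == "D4a"


def test_narrow_caps_at_top_five_scored():
    candidates = [f"g{i}" for i in range(9)]
    from mitotrack.classify import CandidateHG, ClassificationResult

    group = [
        CandidateHG(g, 1, 0, 1, 1, frozenset(), frozenset(), score=9 - i, h=1, rank_group=1)
        for i, g in enumerate(candidates)
    ]
    from mitotrack import HaplogroupNode, HaplogroupTree

    tree = HaplogroupTree(
        [HaplogroupNode("r", None, [])]
        + [HaplogroupNode(g, "r", []) for g in candidates]
    )
    result = ClassificationResult("s", [group])
    names, _ = narrow_candidates(result, tree)
    assert names == candidates[:5]


# -- amplicon proposal --------------------------------------------------


def test_forced_single_amplicon_choice(toy_tree):
    panel = [AmpliconDef("x", 2900, 3300, "coding")]
    proposals, status = propose_targets(
        ["D4a", "D4b"], toy_tree, [(16024, 16569), (1, 576)], panel
    )
    assert status == "ok"
    assert [amp.name for amp, _ in proposals] == ["x"]
    resolved = proposals[0][1]
    assert {format_variant(v) for v in resolved} == {"3010", "3012"}


def test_covered_discriminators_need_no_new_amplicons(toy_tree):
    proposals, status = propose_targets(
        ["D4a", "D4b"], toy_tree, [(1, 16569)], tile_panel()
    )
    assert proposals == [] and status == "already_covered"


def test_non_discriminable_candidates_flagged():
    from mitotrack import HaplogroupNode, HaplogroupTree
    from mitotrack.variants import parse_variant_tokens

    tree = HaplogroupTree(
        [
            HaplogroupNode("r", None, []),
            HaplogroupNode("p", "r", parse_variant_tokens("73")),
            HaplogroupNode("q", "p", []),  # profile-identical to p
        ]
    )
    proposals, status = propose_targets(["p", "q"], tree, [(1, 576)], tile_panel())
    assert proposals == [] and status == "non_discriminable"


def test_panel_outside_variants_flagged(toy_tree):
    panel = [AmpliconDef("far", 10000, 10400, "coding")]
    proposals, status = propose_targets(
        ["D4a", "D4b"], toy_tree, [(16024, 16569), (1, 576)], panel
    )
    assert proposals == [] and status == "non_discriminable"


def test_greedy_prefers_amplicon_splitting_most(toy_tree):
    # one amplicon covers both 3010 and 3012; singles cover one each
    panel = [
        AmpliconDef("single1", 3000, 3011, "coding"),
        AmpliconDef("both", 2900, 3300, "coding"),
        AmpliconDef("single2", 3011, 3100, "coding"),
    ]
    proposals, status = propose_targets(
        ["D4", "D4a", "D4b"], toy_tree, [(16024, 16569), (1, 576)], panel
    )
    assert status == "ok"
    assert [amp.name for amp, _ in proposals] == ["both"]


def test_panel_tsv_round_trip(tmp_path):
    panel = [AmpliconDef("a", 100, 500, "CR"), AmpliconDef("b", 16400, 120, "CR")]
    path = tmp_path / "panel.tsv"
    save_panel(panel, path)
    loaded = read_panel(path)
    assert loaded == panel
    assert loaded[1].intervals() == ((16400, 16569), (1, 120))


# -- tracking loop ------------------------------------------------------


def test_two_track_resolution_of_cr_ambiguous_siblings(toy_tree, reference):
    """CR-tied siblings resolve in 2 tracks with 1 added coding amplicon."""
    outcome = simulate_tracking("D4a", toy_tree, None, reference)
    assert outcome.final_hg == "D4a"
    assert outcome.agreed_with_truth is True
    assert outcome.tracks_used == 2
    assert outcome.amplicons_used == len(DEFAULT_CR_AMPLICONS) + 1
    assert not outcome.stalled


def test_unique_cr_signature_resolves_in_one_track(toy_tree, reference):
    # E1 is a leaf whose control-region profile no other node shares
    outcome = simulate_tracking("E1", toy_tree, None, reference)
    assert outcome.final_hg == "E1"
    assert outcome.tracks_used == 1
    assert outcome.amplicons_used == len(DEFAULT_CR_AMPLICONS)


def test_track_update_merges_evidence(toy_tree, reference):
    cr_frags = amplicon_fragments(toy_tree, "D4a", reference, DEFAULT_CR_AMPLICONS)
    state = start_tracking(cr_frags, toy_tree, None, reference, sample_id="s")
    assert set(state.candidates) == {"D4", "D4a", "D4b"}
    assert not state.finished
    coding = [Fragment("amp", haplogroup_fragment(toy_tree, "D4a", reference, (2900, 3300)))]
    state2 = track_update(state, coding, toy_tree, None, reference, panel=tile_panel())
    assert state2.finished and state2.final_hg == "D4a"
    assert state2.track_index == 2
    assert len(state2.history) == 2


def test_uninformative_fragment_keeps_candidates(toy_tree, reference):
    cr_frags = amplicon_fragments(toy_tree, "D4a", reference, DEFAULT_CR_AMPLICONS)
    state = start_tracking(cr_frags, toy_tree, None, reference, sample_id="s")
    boring = [Fragment("dull", haplogroup_fragment(toy_tree, "D4a", reference, (10000, 10300)))]
    state2 = track_update(state, boring, toy_tree, None, reference)
    assert set(state2.candidates) == set(state.candidates)
    assert state2.track_index == state.track_index + 1


def test_update_after_finish_rejected(toy_tree, reference):
    frags = [Fragment("full", haplogroup_fragment(toy_tree, "B1", reference, (1, 16569)))]
    state = start_tracking(frags, toy_tree, None, reference)
    assert state.finished
    with pytest.raises(TrackingError, match="finished"):
        track_update(state, frags, toy_tree, None, reference)


def test_profile_identical_nodes_stall_to_mrca(reference):
    from mitotrack import HaplogroupNode, HaplogroupTree
    from mitotrack.variants import parse_variant_tokens

    tree = HaplogroupTree(
        [
            HaplogroupNode("r", None, []),
            HaplogroupNode("p", "r", parse_variant_tokens("16311")),
            HaplogroupNode("q", "p", []),  # ancestor/descendant, no splitter
        ]
    )
    outcome = simulate_tracking("q", tree, None, reference)
    assert outcome.final_hg == "q"  # deepest of the unsplittable chain
    assert outcome.agreed_with_truth is True


def test_simulate_all_covers_every_haplogroup(toy_tree, reference):
    frame = simulate_all(toy_tree, None, reference)
    assert len(frame) == len(toy_tree) - 1
    assert frame["agreed"].all()
    # deterministic: a second run reproduces the table exactly
    frame2 = simulate_all(toy_tree, None, reference)
    assert frame.equals(frame2)


def test_amplicons_non_increasing_under_panel_densification(toy_tree, reference):
    sparse = tile_panel(size=800, overlap=40)
    dense = sparse + tile_panel(size=300, overlap=30)  # superset panel
    for hg in ("D4a", "D4b", "A1a"):
        out_sparse = simulate_tracking(hg, toy_tree, None, reference, coding_panel=sparse)
        out_dense = simulate_tracking(hg, toy_tree, None, reference, coding_panel=dense)
        assert out_dense.amplicons_used <= out_sparse.amplicons_used
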