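"""Synthetic haplogroup trees, corpora and fragmented samples.

These generators stand in for the real Phylotree export and GenBank corpus,
which cannot be redistributed: random nomenclature-style trees over the
packaged reference, sequence corpora with recurrent private variants, and
fragmented samples with an optional ancient-DNA-style terminal deamination
model (C->T at 5' ends, G->A at 3' ends, exponentially decaying with
distance from the end). All randomness flows from the single seed in
:class:`SynthSpec`.

The damage model is a configurable synthetic stand-in: real ancient-DNA
inputs to this kind of tool are PCR consensus sequences in which most
deamination has been averaged out, so the default damage rate is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .align import Fragment, build_sample_profile
from .classify import classify
from .hapdb import CorpusRecord
from .phylotree import (
    HaplogroupNode,
    HaplogroupTree,
    haplogroup_fragment,
    natural_key,
)
from .reference import (
    CR_RANGES,
    DEFAULT_HOTSPOT_MASK,
    REFERENCE_LENGTH,
    packaged_reference,
)
from .tracking import DEFAULT_CR_AMPLICONS
from .variants import Variant, VariantKind, format_variant

#: reference regions kept variant-free in synthetic trees: masked hotspot
#: positions, the placeholder, and the engineered homopolymer tracts (where
#: 3'-shift normalization would rename naively placed variants)
_EXCLUDED_SPANS = ((303, 316), (523, 525), (16184, 16194), (3106, 3108), (16519, 16519))


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for synthetic data generation."""

    n_haplogroups: int = 50
    branch_variants: Tuple[int, int] = (1, 3)  # inclusive range per branch
    cr_fraction: float = 0.4  # chance a branch variant falls in the CR
    cr_ambiguous_pairs: int = 0  # sibling pairs sharing their CR profile
    fragments_per_sample: int = 4
    fragment_length: Tuple[float, float] = (150.0, 40.0)  # mean, sd (bp)
    damage_rate: float = 0.0  # terminal deamination probability at the end base
    damage_decay: float = 3.0  # e-folding distance (bases) of the damage rate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_haplogroups < 2:
            raise ValueError("need at least 2 haplogroups")
        if not (0.0 <= self.damage_rate <= 1.0 and 0.0 <= self.cr_fraction <= 1.0):
            raise ValueError("rates must lie in [0, 1]")


def _position_pools(reference: str) -> Tuple[List[int], List[int]]:
    def excluded(p: int) -> bool:
        return any(a <= p <= b for a, b in _EXCLUDED_SPANS) or p in DEFAULT_HOTSPOT_MASK

    cr, coding = [], []
    for p in range(1, len(reference) + 1):
        if excluded(p):
            continue
        if any(a <= p <= b for a, b in CR_RANGES):
            cr.append(p)
        else:
            coding.append(p)
    return cr, coding


def _child_name(parent: str, ordinal: int, root: str) -> str:
    if parent == root:
        # top-level clades: A, B, ..., Z, AA, AB, ...
        name = ""
        o = ordinal
        while True:
            name = chr(ord("A") + o % 26) + name
            o = o // 26 - 1
            if o < 0:
                break
        return name
    if parent[-1].isdigit():
        return parent + chr(ord("a") + ordinal)
    return parent + str(ordinal + 1)


def _draw_variant(rng: np.random.Generator, pos: int, reference: str) -> Variant:
    ref_base = reference[pos - 1]
    r = rng.random()
    if r < 0.80:
        return Variant(pos, VariantKind.TRANSITION)
    if r < 0.90:
        partner = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_base]
        choices = [b for b in "ACGT" if b not in (ref_base, partner)]
        return Variant(pos, VariantKind.TRANSVERSION, choices[rng.integers(len(choices))])
    if r < 0.95 and reference[pos - 1] != reference[pos]:  # 3'-most deletion only
        return Variant(pos, VariantKind.DELETION)
    base = "ACGT"[rng.integers(4)]
    if pos < len(reference) and reference[pos] == base:
        base = {"A": "C", "C": "A", "G": "T", "T": "G"}[base]  # keep 3'-most anchor
    return Variant(pos, VariantKind.INSERTION, base, 1)


def generate_toy_tree(
    spec: SynthSpec, reference: Optional[str] = None
) -> Tuple[HaplogroupTree, pd.DataFrame]:
    """Random nomenclature-style haplogroup tree with unique profiles.

    Every branch introduces at least one variant at a previously unused
    position, so cumulative profiles are unique — except for the requested
    ``cr_ambiguous_pairs``: sibling pairs whose branches carry only coding
    variants, making their control-region profiles identical (the
    multi-candidate test case). Returns the tree and a truth table.
    """
    reference = reference if reference is not None else packaged_reference()
    rng = np.random.default_rng(spec.seed)
    cr_pool, coding_pool = _position_pools(reference)
    rng.shuffle(cr_pool)
    rng.shuffle(coding_pool)
    lo, hi = spec.branch_variants
    n_regular = spec.n_haplogroups - 1 - 2 * spec.cr_ambiguous_pairs
    if n_regular < 1:
        raise ValueError("cr_ambiguous_pairs leave no room for regular nodes")
    needed = (spec.n_haplogroups - 1) * hi
    if needed > len(cr_pool) + len(coding_pool):
        raise ValueError("more branch variants requested than available positions")

    root = "mt-MRCA"
    nodes: Dict[str, HaplogroupNode] = {root: HaplogroupNode(root, None, [])}
    child_count: Dict[str, int] = {root: 0}
    ambiguous: Set[str] = set()

    def take(pool: List[int]) -> int:
        if not pool:
            raise ValueError("position pool exhausted")
        return pool.pop()

    def add_node(parent: str, variants: List[Variant]) -> str:
        name = _child_name(parent, child_count[parent], root)
        child_count[parent] += 1
        child_count[name] = 0
        nodes[name] = HaplogroupNode(name, parent, variants)
        return name

    for i in range(n_regular):
        existing = sorted(nodes, key=natural_key)
        parent = root if i == 0 else existing[int(rng.integers(len(existing)))]
        k = int(rng.integers(lo, hi + 1))
        variants: List[Variant] = []
        for j in range(k):
            force_cr = parent == root and j == 0  # top clades stay CR-visible
            use_cr = force_cr or (rng.random() < spec.cr_fraction and cr_pool)
            pool = cr_pool if use_cr and cr_pool else coding_pool
            variants.append(_draw_variant(rng, take(pool), reference))
        add_node(parent, variants)

    for _ in range(spec.cr_ambiguous_pairs):
        internal = [n for n in sorted(nodes, key=natural_key) if n != root]
        parent = internal[int(rng.integers(len(internal)))]
        for _ in range(2):
            v = Variant(take(coding_pool), VariantKind.TRANSITION)
            ambiguous.add(add_node(parent, [v]))

    tree = HaplogroupTree(list(nodes.values()))
    rows = [
        {
            "haplogroup": name,
            "parent": node.parent or "",
            "depth": tree.depth(name),
            "branch_variants": " ".join(format_variant(v) for v in node.branch_variants),
            "cr_ambiguous": name in ambiguous,
        }
        for name, node in sorted(nodes.items(), key=lambda kv: natural_key(kv[0]))
    ]
    return tree, pd.DataFrame(rows)


# -- sample generation --------------------------------------------------


def _apply_damage(sequence: str, rng: np.random.Generator, spec: SynthSpec) -> str:
    if spec.damage_rate == 0.0:
        return sequence
    bases = list(sequence)
    n = len(bases)
    for j in range(n):
        p5 = spec.damage_rate * math.exp(-j / spec.damage_decay)
        p3 = spec.damage_rate * math.exp(-(n - 1 - j) / spec.damage_decay)
        if bases[j] == "C" and rng.random() < p5:
            bases[j] = "T"
        elif bases[j] == "G" and rng.random() < p3:
            bases[j] = "A"
    return "".join(bases)


def _circular_fragment(
    tree: HaplogroupTree, hg: str, reference: str, start: int, length: int
) -> str:
    """Fragment of the haplogroup sequence starting at a 1-based rCRS position."""
    end = start + length - 1
    if end <= REFERENCE_LENGTH:
        return haplogroup_fragment(tree, hg, reference, (start, end))
    head = haplogroup_fragment(tree, hg, reference, (start, REFERENCE_LENGTH))
    tail = haplogroup_fragment(tree, hg, reference, (1, end - REFERENCE_LENGTH))
    return head + tail


def generate_sample(
    tree: HaplogroupTree,
    hg: str,
    spec: SynthSpec,
    reference: Optional[str] = None,
    mode: str = "cr",
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[Fragment], Dict[str, object]]:
    """Fragments of one haplogroup's sequence plus a truth record.

    Modes: ``cr`` (the four control-region amplicons), ``tiling`` (2 kb
    windows covering the genome) or ``random`` (random starts and lengths
    per the spec's distributions, origin-aware).
    """
    reference = reference if reference is not None else packaged_reference()
    if hg not in tree:
        raise ValueError(f"unknown haplogroup {hg!r}")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    fragments: List[Fragment] = []
    if mode == "cr":
        for amp in DEFAULT_CR_AMPLICONS:
            for j, (a, b) in enumerate(amp.intervals()):
                seq = haplogroup_fragment(tree, hg, reference, (a, b))
                fragments.append(Fragment(f"{hg}.{amp.name}.{j}", _apply_damage(seq, rng, spec)))
    elif mode == "tiling":
        step, size = 1900, 2000
        for i, start in enumerate(range(1, REFERENCE_LENGTH, step)):
            end = min(start + size - 1, REFERENCE_LENGTH)
            seq = haplogroup_fragment(tree, hg, reference, (start, end))
            fragments.append(Fragment(f"{hg}.tile{i:02d}", _apply_damage(seq, rng, spec)))
    elif mode == "random":
        mean, sd = spec.fragment_length
        for i in range(spec.fragments_per_sample):
            length = int(np.clip(rng.normal(mean, sd), 60, 1000))
            start = int(rng.integers(1, REFERENCE_LENGTH + 1))
            seq = _circular_fragment(tree, hg, reference, start, length)
            fragments.append(Fragment(f"{hg}.rnd{i:02d}", _apply_damage(seq, rng, spec)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    truth = {"haplogroup": hg, "mode": mode, "n_fragments": len(fragments)}
    return fragments, truth


def generate_corpus(
    tree: HaplogroupTree,
    spec: SynthSpec,
    reference: Optional[str] = None,
    samples_per_hg: Tuple[int, int] = (2, 6),
    cr_probability: float = 0.6,
    private_variant_rate: float = 0.4,
) -> Tuple[List[CorpusRecord], pd.DataFrame]:
    """Sequence corpus for haplotype-DB construction.

    Each haplogroup contributes a random number of samples, each either a
    control-region sequence or a few-kb partial-genome window. Each
    haplogroup is assigned one recurrent private site; a sample carries the
    extra transition there with probability ``private_variant_rate`` —
    recurrent private haplotypes are what give the frequency score its
    discriminating power.
    """
    reference = reference if reference is not None else packaged_reference()
    rng = np.random.default_rng(spec.seed + 1)
    cr_pool, coding_pool = _position_pools(reference)
    used = {v.position for n in tree.nodes for v in tree.nodes[n].branch_variants}
    free_coding = [p for p in coding_pool if p not in used]
    rng.shuffle(free_coding)
    free_cr = [p for p in cr_pool if p not in used]
    rng.shuffle(free_cr)

    records: List[CorpusRecord] = []
    rows = []
    for hg in sorted(tree.nodes, key=natural_key):
        if hg == tree.root:
            continue
        private_pos = free_cr.pop() if free_cr else free_coding.pop()
        n_samples = int(rng.integers(samples_per_hg[0], samples_per_hg[1] + 1))
        for s in range(n_samples):
            is_cr = rng.random() < cr_probability
            extra = rng.random() < private_variant_rate
            profile = set(tree.cumulative_profile(hg))
            if extra:
                profile.add(Variant(private_pos, VariantKind.TRANSITION))
            from .phylotree import apply_variants

            if is_cr:
                a, b = 16024, 576
                head = apply_variants(
                    reference,
                    [v for v in profile if 16024 <= v.position <= 16569],
                    interval=(16024, 16569),
                )
                tail = apply_variants(
                    reference,
                    [v for v in profile if 1 <= v.position <= 576],
                    interval=(1, 576),
                )
                seq = head + tail
            else:
                start = int(rng.integers(577, 16023 - 4000))
                a, b = start, start + int(rng.integers(2500, 4000))
                seq = apply_variants(
                    reference,
                    [v for v in profile if a <= v.position <= b],
                    interval=(a, b),
                )
            rid = f"{hg}_s{s:02d}"
            records.append(CorpusRecord(rid, seq))
            rows.append(
                {
                    "id": rid,
                    "haplogroup": hg,
                    "region": "CR" if is_cr else "genomic",
                    "has_private": extra,
                    "private_position": private_pos,
                }
            )
    return records, pd.DataFrame(rows)


# -- agreement evaluation ----------------------------------------------


def evaluate_agreement(
    samples: Sequence[Tuple[str, Sequence[Fragment], str]],
    tree: HaplogroupTree,
    db=None,
    reference: Optional[str] = None,
    max_rank: int = 30,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Cumulative per-rank agreement of classifications with the truth.

    ``samples`` is a list of (sample_id, fragments, true haplogroup). The
    returned curve gives, for each rank r, how many samples had their true
    haplogroup within the top r ranked candidates; the summary reports the
    top-1 agreement rate in percent.
    """
    if not samples:
        raise ValueError("need at least one truth-labeled sample")
    reference = reference if reference is not None else packaged_reference()
    ranks: List[Optional[int]] = []
    for sample_id, fragments, true_hg in samples:
        profile = build_sample_profile(list(fragments), reference, sample_id=sample_id)
        result = classify(profile, tree, db)
        ranks.append(result.rank_of(true_hg))
    n = len(ranks)
    rows = []
    for r in range(1, max_rank + 1):
        agreed = sum(1 for k in ranks if k is not None and k <= r)
        rows.append({"rank": r, "cumulative_agreed": agreed, "cumulative_rate": 100.0 * agreed / n})
    curve = pd.DataFrame(rows)
    top1 = 100.0 * sum(1 for k in ranks if k == 1) / n
    summary = {"n_samples": float(n), "top1_agreement_pct": top1}
    return curve, summary
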