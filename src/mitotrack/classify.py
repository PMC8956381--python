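"""Haplogroup ranking by fragment-range-aware variant identity.

For a sample with variant set of size ``Vs`` and covered reference ranges
``R``, each haplogroup ``g`` with cumulative profile ``P(g)`` gets

* ``Vp`` — profile variants present among the sample variants,
* ``Vm`` — profile variants absent from the sample whose positions fall
  inside ``R`` (a profile variant outside the sequenced ranges is not
  evidence against ``g``),
* variant identity ``(Vp - Vm) / Vs``.

Haplogroups sharing one of the four highest distinct identity values form
Rank Groups 1-4. Within a rank group, candidates are ordered by the
haplotype-frequency score

    score(g) = sum_extras He(g,v)/H(g) + sum_missing Hm(g,v)/H(g)

where ``H(g)`` is how often ``g`` was assigned in the haplotype database,
``He(g,v)`` how many of those assignments carried the extra variant ``v``
and ``Hm(g,v)`` how many lacked the profile variant ``v``. A high score
means the sample's private variants are familiar haplotypes of ``g``.

Identity values are compared as exact rationals so that rank-group
membership (defined by identity equality) is never blurred by floating
point. A sample with no variants has undefined identity; such samples are
ranked by ascending ``Vm`` instead, so a reference-identical sample still
classifies toward the shallow-profile clades.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import FrozenSet, Iterable, List, Optional, Tuple

import pandas as pd

from .align import SampleProfile
from .phylotree import HaplogroupTree, natural_key
from .reference import position_in_ranges
from .variants import Variant, format_variant, format_variants


@dataclass(frozen=True)
class CandidateHG:
    haplogroup: str
    vp: int
    vm: int
    vs: int
    identity: Optional[Fraction]  # None when Vs == 0
    extras: FrozenSet[Variant]
    missing: FrozenSet[Variant]
    score: float = 0.0
    h: int = 0
    rank_group: int = 0


@dataclass
class ClassificationResult:
    sample_id: str
    rank_groups: List[List[CandidateHG]]
    qc_flags: List[str] = field(default_factory=list)
    dropped_ties: int = 0  # haplogroups beyond the 4th distinct identity

    def flatten(self) -> List[CandidateHG]:
        return [c for group in self.rank_groups for c in group]

    @property
    def best(self) -> Optional[str]:
        flat = self.flatten()
        return flat[0].haplogroup if flat else None

    def rank_group_1(self) -> List[str]:
        return [c.haplogroup for c in self.rank_groups[0]] if self.rank_groups else []

    def rank_of(self, haplogroup: str) -> Optional[int]:
        """1-based rank of a haplogroup in the flattened ordering."""
        for i, c in enumerate(self.flatten(), start=1):
            if c.haplogroup == haplogroup:
                return i
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "haplogroup": c.haplogroup,
                "rank_group": c.rank_group,
                "Vp": c.vp,
                "Vm": c.vm,
                "Vs": c.vs,
                "identity": float(c.identity) if c.identity is not None else float("nan"),
                "score": c.score,
                "H": c.h,
                "extras": format_variants(c.extras),
                "missing": format_variants(c.missing),
            }
            for c in self.flatten()
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "haplogroup", "rank_group", "Vp", "Vm", "Vs",
                "identity", "score", "H", "extras", "missing",
            ],
        )


def variant_identity(
    sample: SampleProfile, profile: Iterable[Variant]
) -> Tuple[int, int, int, Optional[Fraction]]:
    """Compute (Vp, Vm, Vs, identity) for one haplogroup profile."""
    profile = frozenset(profile)
    present = profile & sample.variants
    vp = len(present)
    missing = {
        v
        for v in profile - sample.variants
        if position_in_ranges(v.position, sample.ranges)
    }
    vm = len(missing)
    vs = sample.vs
    identity = Fraction(vp - vm, vs) if vs > 0 else None
    return vp, vm, vs, identity


def eq2_score(haplogroup: str, extras: Iterable[Variant], missing: Iterable[Variant], db) -> float:
    """Private-variant frequency score; 0 with no database or unseen keys."""
    if db is None:
        return 0.0
    h = db.h(haplogroup)
    if h == 0:
        return 0.0
    total = sum(db.he(haplogroup, format_variant(v)) for v in extras)
    total += sum(db.hm(haplogroup, format_variant(v)) for v in missing)
    return total / h


def classify(
    sample: SampleProfile,
    tree: HaplogroupTree,
    db=None,
    max_rank_groups: int = 4,
    qc: bool = True,
    qc_depth_threshold: int = 2,
) -> ClassificationResult:
    """Rank every haplogroup of the tree for one sample profile."""
    if not sample.ranges:
        raise ValueError("sample profile covers no reference ranges")
    candidates: List[CandidateHG] = []
    for name in tree.nodes:
        profile = tree.cumulative_profile(name)
        vp, vm, vs, identity = variant_identity(sample, profile)
        extras = sample.variants - profile
        missing = frozenset(
            v
            for v in profile - sample.variants
            if position_in_ranges(v.position, sample.ranges)
        )
        score = eq2_score(name, extras, missing, db)
        h = db.h(name) if db is not None else 0
        candidates.append(
            CandidateHG(name, vp, vm, vs, identity, frozenset(extras), missing, score, h)
        )

    if sample.vs > 0:
        keys = sorted({c.identity for c in candidates}, reverse=True)

        def key_of(c: CandidateHG):
            return c.identity

    else:  # undefined identity: rank by fewest in-range missing variants
        keys = sorted({c.vm for c in candidates})

        def key_of(c: CandidateHG):
            return c.vm

    kept_keys = keys[:max_rank_groups]
    dropped = sum(1 for c in candidates if key_of(c) not in kept_keys)
    groups: List[List[CandidateHG]] = []
    for gi, key in enumerate(kept_keys, start=1):
        members = [c for c in candidates if key_of(c) == key]
        members.sort(key=lambda c: (-c.score, -c.h, natural_key(c.haplogroup)))
        groups.append(
            [
                CandidateHG(
                    c.haplogroup, c.vp, c.vm, c.vs, c.identity,
                    c.extras, c.missing, c.score, c.h, gi,
                )
                for c in members
            ]
        )
    result = ClassificationResult(sample.sample_id, groups, dropped_ties=dropped)
    if qc:
        result.qc_flags = qc_recombination(sample, tree, result, db, qc_depth_threshold)
    return result


def qc_recombination(
    sample: SampleProfile,
    tree: HaplogroupTree,
    result: ClassificationResult,
    db=None,
    depth_threshold: int = 2,
) -> List[str]:
    """Flag samples whose fragments support mutually distant clades.

    Each fragment with at least one variant is classified on its own; if the
    most recent common ancestor of the per-fragment best haplogroups sits
    above ``depth_threshold`` while the joint best haplogroup is at or below
    it, the fragments disagree about the lineage — the signature of an
    artificial recombinant (e.g. a sample assembled from two individuals).
    Samples with fewer than two variant-bearing fragments are not checkable.
    """
    informative = [
        (fid, variants, ranges)
        for fid, variants, ranges in sample.fragment_calls
        if variants
    ]
    if len(informative) < 2:
        return []
    joint = result.best
    if joint is None or tree.depth(joint) < depth_threshold:
        return []
    bests: List[Tuple[str, str]] = []
    for fid, variants, ranges in informative:
        mini = SampleProfile(fid, frozenset(variants), tuple(ranges))
        res = classify(mini, tree, db, qc=False)
        if res.best is not None:
            bests.append((fid, res.best))
    if len(bests) < 2:
        return []
    mrca = tree.mrca([b for _, b in bests])
    if tree.depth(mrca) < depth_threshold:
        detail = ", ".join(f"{fid}->{hg}" for fid, hg in bests)
        return [
            f"possible artificial recombination: fragment assignments ({detail}) "
            f"meet only at {mrca!r} (depth {tree.depth(mrca)}) while the joint "
            f"assignment {joint!r} is at depth {tree.depth(joint)}"
        ]
    return []
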