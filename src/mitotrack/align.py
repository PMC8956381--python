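"""Fragment-to-reference alignment and variant calling.

Fragments are aligned to the mitochondrial reference with an affine-gap
global aligner (Gotoh / Needleman-Wunsch with gap open and gap extension
penalties), run semi-globally on the reference side: leading and trailing
reference overhangs are free, so a short fragment settles at its true locus
without end-gap cost. The dynamic programming itself is delegated to
Biopython's C ``PairwiseAligner`` configured for this scoring scheme.

Because the mitochondrial genome is circular and the control region spans
the origin, fragments are located on a doubled reference and coordinates
are folded back; a covered range crossing the origin splits into two
intervals. Fragment placement is seeded with exact k-mer diagonal voting so
that only a narrow reference window enters the DP; alignment falls back to
the full (doubled) reference when seeding fails.

Alignment columns are converted to Phylotree-notation variants:
substitutions are classed transition/transversion by purine–pyrimidine
partnership, indels are right-shifted to their 3'-most equivalent placement
before naming, IUPAC-ambiguous query bases yield no call, and hotspot-mask
positions are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from Bio import Align

from .reference import (
    DEFAULT_HOTSPOT_MASK,
    merge_ranges,
    position_in_ranges,
    seed_window,
)
from .variants import (
    TRANSITION_PARTNER,
    Variant,
    VariantKind,
    format_variant,
    parse_variant_tokens,
)


class AlignmentError(ValueError):
    pass


class ProfileConflictError(ValueError):
    """Overlapping fragments disagree on the state of one or more positions."""

    def __init__(self, conflicts: Sequence[Tuple[int, str, str]]):
        self.conflicts = list(conflicts)
        detail = "; ".join(f"position {p}: {a} vs {b}" for p, a, b in self.conflicts)
        super().__init__(f"conflicting calls between overlapping fragments: {detail}")


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap scoring. A gap of length L costs open + (L-1) * extend."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0):
            raise AlignmentError("require gap_open <= gap_extend <= 0")
        if self.match <= 0 or self.mismatch >= self.match:
            raise AlignmentError("require mismatch < match and match > 0")


DEFAULT_PARAMS = AlignParams()


@dataclass(frozen=True)
class Fragment:
    id: str
    sequence: str
    declared_range: Optional[Tuple[Tuple[int, int], ...]] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise AlignmentError(f"fragment {self.id!r} has an empty sequence")
        bad = set(self.sequence.upper()) - set("ACGTRYSWKMBDHVN")
        if bad:
            raise AlignmentError(f"fragment {self.id!r} has non-IUPAC characters {sorted(bad)}")


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    aligned_query: str
    aligned_reference: str
    reference_span: Tuple[int, int]  # 1-based inclusive, in the supplied reference


@dataclass(frozen=True)
class SampleProfile:
    """A sample's called variants plus the reference ranges its fragments cover."""

    sample_id: str
    variants: FrozenSet[Variant]
    ranges: Tuple[Tuple[int, int], ...]
    warnings: Tuple[str, ...] = ()
    fragment_calls: Tuple[Tuple[str, FrozenSet[Variant], Tuple[Tuple[int, int], ...]], ...] = ()

    @property
    def vs(self) -> int:
        return len(self.variants)

    @classmethod
    def from_tokens(cls, sample_id: str, tokens: str, ranges) -> "SampleProfile":
        variants = frozenset(parse_variant_tokens(tokens))
        return cls(sample_id, variants, tuple(merge_ranges(ranges)))


# -- aligner ------------------------------------------------------------


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = params.match
    a.mismatch_score = params.mismatch
    a.open_gap_score = params.gap_open
    a.extend_gap_score = params.gap_extend
    # semi-global: unaligned reference overhangs (gaps at the query's ends
    # in the reference row's frame) cost nothing
    a.end_deletion_score = 0.0
    return a


def align_gotoh(query: str, reference: str, params: AlignParams = DEFAULT_PARAMS) -> AlignmentResult:
    """Optimal affine-gap alignment of ``query`` within ``reference``.

    Global over the query, free end gaps on the reference, deterministic
    first-traceback tie-break.
    """
    if not query or not reference:
        raise AlignmentError("empty sequence passed to aligner")
    query = query.upper()
    reference = reference.upper()
    aligner = _make_aligner(params)
    alignments = aligner.align(reference, query)
    best = alignments[0]
    aligned_ref = best[0]
    aligned_query = best[1]
    span = _reference_span(aligned_ref, aligned_query)
    return AlignmentResult(float(alignments.score), aligned_query, aligned_ref, span)


def _reference_span(aligned_ref: str, aligned_query: str) -> Tuple[int, int]:
    rpos = 0
    start = end = None
    for rc, qc in zip(aligned_ref, aligned_query):
        if rc != "-":
            rpos += 1
        if qc != "-" and rc != "-":
            if start is None:
                start = rpos
            end = rpos
    if start is None:  # query aligned entirely into gaps (degenerate)
        return (1, 0)
    return (start, end)


# -- variant calling ----------------------------------------------------


def call_variants(
    aln: AlignmentResult,
    hotspot_mask: Iterable = DEFAULT_HOTSPOT_MASK,
    reference_start: int = 1,
) -> Tuple[Set[Variant], Tuple[int, int]]:
    """Convert an alignment into Phylotree-notation variants.

    ``reference_start`` is the 1-based coordinate of the first base of
    ``aln.aligned_reference`` in the genome the caller ultimately reports
    against. Returns the variant set and the covered interval (both in that
    coordinate frame). Indels are right-shifted to their 3'-most equivalent
    placement; ambiguous query bases and masked positions produce no call.
    """
    mask_positions = {m for m in hotspot_mask if isinstance(m, int)}
    mask_tokens = {m for m in hotspot_mask if isinstance(m, str)}
    window = aln.aligned_reference.replace("-", "")
    offset = reference_start - 1  # window[p - 1] is genome position p + offset

    def refbase(pos: int) -> str:
        return window[pos - offset - 1]

    cols = list(zip(aln.aligned_reference, aln.aligned_query))
    qcols = [i for i, (_, qc) in enumerate(cols) if qc != "-"]
    if not qcols:
        raise AlignmentError("query is entirely unaligned")
    qfirst, qlast = qcols[0], qcols[-1]

    subs: List[Tuple[int, str]] = []
    deletions: List[List[int]] = []  # runs of consecutive deleted positions
    insertions: List[Tuple[int, List[str]]] = []  # (anchor position, bases)
    covered_start = covered_end = None
    rpos = offset
    for i, (rc, qc) in enumerate(cols):
        if rc != "-":
            rpos += 1
        if i < qfirst or i > qlast:
            continue
        if rc != "-" and qc != "-":
            if covered_start is None:
                covered_start = rpos
            covered_end = rpos
            if qc != rc:
                if qc not in "ACGT" or rc not in "ACGT":
                    continue  # ambiguity or placeholder: no call
                subs.append((rpos, qc))
        elif rc != "-" and qc == "-":
            if covered_start is None:
                covered_start = rpos
            covered_end = rpos
            if deletions and deletions[-1][-1] == rpos - 1:
                deletions[-1].append(rpos)
            else:
                deletions.append([rpos])
        elif rc == "-" and qc != "-":
            if qc not in "ACGT":
                continue
            if insertions and insertions[-1][0] == rpos and cols[i - 1][0] == "-":
                insertions[-1][1].append(qc)
            else:
                insertions.append((rpos, [qc]))
    if covered_start is None:
        raise AlignmentError("no aligned reference positions")

    out: Set[Variant] = set()
    for pos, base in subs:
        rb = refbase(pos)
        if TRANSITION_PARTNER.get(rb) == base:
            out.add(Variant(pos, VariantKind.TRANSITION))
        else:
            out.add(Variant(pos, VariantKind.TRANSVERSION, base))
    window_end = offset + len(window)
    for run in deletions:
        p, k = run[0], len(run)
        limit = min(covered_end, window_end - k)
        while p <= limit and p + k <= window_end and refbase(p) == refbase(p + k):
            p += 1
        out.update(Variant(p + j, VariantKind.DELETION) for j in range(k))
    for anchor, bases in insertions:
        p, s = anchor, list(bases)
        while p + 1 <= min(covered_end, window_end) and refbase(p + 1) == s[0]:
            p += 1
            s = s[1:] + [s[0]]
        if p == 0:
            continue  # insertion before position 1: unanchorable, drop
        out.update(
            Variant(p, VariantKind.INSERTION, b, j + 1) for j, b in enumerate(s)
        )
    out = {
        v
        for v in out
        if v.position not in mask_positions and format_variant(v) not in mask_tokens
    }
    return out, (covered_start, covered_end)


# -- fragment pipeline --------------------------------------------------


def _fold_circular(
    variants: Set[Variant], span: Tuple[int, int], length: int
) -> Tuple[Set[Variant], List[Tuple[int, int]]]:
    """Map doubled-reference coordinates back onto the circular genome."""

    def fold(pos: int) -> int:
        return pos - length if pos > length else pos

    folded = {
        Variant(fold(v.position), v.kind, v.derived, v.insertion_index, v.back_mutation)
        for v in variants
    }
    a, b = span
    if a > length:
        ranges = [(a - length, b - length)]
    elif b > length:
        ranges = [(a, length), (1, b - length)]
    else:
        ranges = [(a, b)]
    return folded, ranges


def call_fragment(
    fragment: Fragment,
    reference: str,
    params: AlignParams = DEFAULT_PARAMS,
    hotspot_mask: Iterable = DEFAULT_HOTSPOT_MASK,
) -> Tuple[Set[Variant], List[Tuple[int, int]], float]:
    """Locate, align and variant-call one fragment against the genome."""
    L = len(reference)
    query = fragment.sequence.upper()
    if len(query) >= 0.8 * L:
        aln = align_gotoh(query, reference, params)
        variants, span = call_variants(aln, hotspot_mask, reference_start=1)
        return variants, [span], aln.score
    doubled = reference + reference
    window = seed_window(query, reference)
    if window is None:
        aln = align_gotoh(query, doubled, params)
        variants, span = call_variants(aln, hotspot_mask, reference_start=1)
    else:
        start, end = window
        aln = align_gotoh(query, doubled[start:end], params)
        variants, span = call_variants(aln, hotspot_mask, reference_start=start + 1)
    folded, ranges = _fold_circular(variants, span, L)
    return folded, ranges, aln.score


def build_sample_profile(
    fragments: Sequence[Fragment],
    reference: str,
    params: AlignParams = DEFAULT_PARAMS,
    hotspot_mask: Iterable = DEFAULT_HOTSPOT_MASK,
    sample_id: str = "sample",
    min_score_fraction: float = 0.5,
) -> SampleProfile:
    """Align and call every fragment, then union variants and merge ranges.

    A fragment whose alignment score falls below ``min_score_fraction`` of
    its perfect-match score is rejected with a warning. Overlapping
    fragments that disagree on the state of a shared position raise
    :class:`ProfileConflictError`.
    """
    if not fragments:
        raise AlignmentError("need at least one fragment")
    warnings: List[str] = []
    calls: List[Tuple[str, Set[Variant], List[Tuple[int, int]]]] = []
    for frag in fragments:
        variants, ranges, score = call_fragment(frag, reference, params, hotspot_mask)
        floor = min_score_fraction * params.match * len(frag.sequence)
        if score < floor:
            warnings.append(
                f"fragment {frag.id!r} rejected: score {score:.1f} below floor {floor:.1f}"
            )
            continue
        calls.append((frag.id, variants, ranges))
    if not calls:
        raise AlignmentError("no fragment aligned above the score floor")
    _check_conflicts(calls)
    all_variants: Set[Variant] = set().union(*(v for _, v, _ in calls))
    all_ranges = merge_ranges(r for _, _, rs in calls for r in rs)
    return SampleProfile(
        sample_id,
        frozenset(all_variants),
        tuple(all_ranges),
        tuple(warnings),
        tuple((fid, frozenset(v), tuple(rs)) for fid, v, rs in calls),
    )


def _check_conflicts(calls) -> None:
    states: Dict[int, Dict[str, str]] = {}
    for fid, variants, _ in calls:
        for v in variants:
            if v.kind in (VariantKind.TRANSITION, VariantKind.TRANSVERSION, VariantKind.DELETION):
                states.setdefault(v.position, {})[fid] = format_variant(v)
    conflicts: List[Tuple[int, str, str]] = []
    for pos in sorted(states):
        tokens: Dict[str, str] = dict(states[pos])
        for fid, _, ranges in calls:
            if fid not in tokens and position_in_ranges(pos, ranges):
                tokens[fid] = f"{fid}:ref"
        distinct = sorted(set(states[pos].values()))
        ref_holders = [t for t in tokens.values() if t.endswith(":ref")]
        if len(distinct) > 1:
            conflicts.append((pos, distinct[0], distinct[1]))
        elif ref_holders:
            conflicts.append((pos, distinct[0], ref_holders[0]))
    if conflicts:
        raise ProfileConflictError(conflicts)
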