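"""Reference genome handling and shared coordinate constants.

The package ships ``data/synthetic_rcrs.fasta``, a deterministic synthetic
stand-in for the 16,569 bp human mitochondrial reference (NC_012920.1): same
length, mtDNA-like base composition, ``N`` at the historical placeholder
position 3107, and homopolymer tracts at the rCRS hotspot landmarks
(303-315, 523-524, 16184-16193). All coordinates in the package are 1-based
inclusive rCRS-style positions. ``load_reference`` accepts a real rCRS FASTA
wherever the synthetic fixture is not wanted.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import Dict, List, Tuple

from Bio import SeqIO

#: expected reference length (rCRS convention)
REFERENCE_LENGTH = 16569

#: historical placeholder position, never called
PLACEHOLDER_POSITION = 3107

#: control region spans the replication origin: 16024..16569 then 1..576
CR_RANGES: Tuple[Tuple[int, int], ...] = ((16024, 16569), (1, 576))

#: positions excluded from variant calling by default (common-practice
#: mtDNA hotspot/placeholder mask; configurable in all calling entry points)
DEFAULT_HOTSPOT_MASK = frozenset({3107, 16519, 309, 315, 523, 524})


def load_reference(path=None) -> str:
    """Load a single-record reference FASTA as an upper-case string.

    With no path, returns the packaged synthetic reference.
    """
    if path is None:
        return packaged_reference()
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


@lru_cache(maxsize=1)
def packaged_reference() -> str:
    with resources.files("mitotrack.data").joinpath("synthetic_rcrs.fasta").open() as fh:
        record = next(SeqIO.parse(fh, "fasta"))
    seq = str(record.seq).upper()
    if len(seq) != REFERENCE_LENGTH:
        raise ValueError("packaged reference has unexpected length")
    return seq


def in_control_region(position: int) -> bool:
    return any(a <= position <= b for a, b in CR_RANGES)


def merge_ranges(ranges) -> List[Tuple[int, int]]:
    """Merge 1-based inclusive intervals into a sorted disjoint list."""
    items = sorted((int(a), int(b)) for a, b in ranges)
    out: List[Tuple[int, int]] = []
    for a, b in items:
        if b < a:
            raise ValueError(f"inverted interval ({a}, {b})")
        if out and a <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def position_in_ranges(position: int, ranges) -> bool:
    return any(a <= position <= b for a, b in ranges)


@lru_cache(maxsize=4)
def _kmer_index(reference: str, k: int) -> Dict[str, List[int]]:
    """Exact k-mer -> start offsets (0-based) over the doubled reference."""
    doubled = reference + reference
    index: Dict[str, List[int]] = {}
    for i in range(len(doubled) - k + 1):
        index.setdefault(doubled[i : i + k], []).append(i)
    return index


def seed_window(query: str, reference: str, k: int = 13, pad: int = 40):
    """Locate a fragment on the doubled reference by k-mer diagonal voting.

    Returns a 0-based ``(start, end)`` window on the doubled reference likely
    to contain the fragment, or ``None`` when no seed matches (caller falls
    back to a full-width alignment).
    """
    if len(query) < k:
        return None
    index = _kmer_index(reference, k)
    votes: Dict[int, int] = {}
    step = max(1, (len(query) - k) // 24)
    for q in range(0, len(query) - k + 1, step):
        for hit in index.get(query[q : q + k], ())[:8]:
            diag = hit - q
            votes[diag] = votes.get(diag, 0) + 1
    if not votes:
        return None
    # cluster nearby diagonals (small indels shift the diagonal slightly)
    best_diag = max(votes, key=lambda d: (votes[d], -d))
    support = sum(c for d, c in votes.items() if abs(d - best_diag) <= 60)
    if support < 2 and len(query) >= 2 * k:
        return None
    start = max(0, best_diag - pad)
    end = min(2 * len(reference), best_diag + len(query) + pad)
    return (start, end)
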