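"""Phylotree-style variant notation.

Variants are expressed relative to the rCRS coordinate system (1-based):

* transition        — bare position, e.g. ``263`` (A<->G or C<->T exchange)
* transversion      — position plus derived base, e.g. ``16318T``
* insertion         — ``<anchor>.<ordinal><base>``, e.g. ``573.1C`` (first base
  inserted after position 573)
* deletion          — ``<position>d``, e.g. ``249d``; range form ``290-291d``
  expands to one deletion per position
* back mutation     — any token suffixed ``!``, e.g. ``16093!`` (reversion to
  the ancestral/reference state at that site)

``parse_variant`` and ``format_variant`` are exact inverses for every valid
single-site token.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, List


class VariantKind(str, Enum):
    TRANSITION = "transition"
    TRANSVERSION = "transversion"
    INSERTION = "insertion"
    DELETION = "deletion"


#: purine/pyrimidine transition partners
TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}

IUPAC_BASES = set("ACGTRYSWKMBDHVN")

_TOKEN_RE = re.compile(
    r"""^(?P<pos>\d+)
        (?:
            \.(?P<idx>\d+)(?P<ins>[ACGT]+)   # insertion
          | (?P<del>d)                       # deletion
          | (?P<base>[ACGT])                 # transversion / explicit base
        )?
        (?P<back>!+)?$""",
    re.VERBOSE,
)

_RANGE_DEL_RE = re.compile(r"^(?P<a>\d+)-(?P<b>\d+)(?P<del>d)(?P<back>!+)?$")


class VariantParseError(ValueError):
    """Raised for a token that does not follow the notation rules."""


@dataclass(frozen=True, order=True)
class Variant:
    """A single mtDNA change relative to the reference."""

    position: int
    kind: VariantKind = VariantKind.TRANSITION
    derived: str = ""
    insertion_index: int = 0
    back_mutation: bool = field(default=False, compare=True)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise VariantParseError(f"position must be >= 1, got {self.position}")
        if self.kind is VariantKind.INSERTION and self.insertion_index < 1:
            raise VariantParseError("insertion requires an ordinal >= 1")
        if self.kind is VariantKind.TRANSVERSION and self.derived not in set("ACGT"):
            raise VariantParseError("transversion requires a derived base")

    @property
    def site_key(self):
        """Identity of the mutated site, ignoring the derived state.

        Used for same-position overwrite and back-mutation cancellation when
        accumulating branch variants along a tree path.
        """
        if self.kind is VariantKind.INSERTION:
            return ("ins", self.position, self.insertion_index)
        if self.kind is VariantKind.DELETION:
            return ("del", self.position)
        return ("sub", self.position)

    def without_back(self) -> "Variant":
        if not self.back_mutation:
            return self
        return Variant(self.position, self.kind, self.derived, self.insertion_index, False)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return format_variant(self)


def parse_variant(token: str) -> Variant:
    """Parse one Phylotree-notation token into a :class:`Variant`."""
    token = token.strip()
    if not token:
        raise VariantParseError("empty variant token")
    m = _TOKEN_RE.match(token)
    if m is None:
        raise VariantParseError(f"malformed variant token: {token!r}")
    pos = int(m.group("pos"))
    back = bool(m.group("back"))
    if m.group("ins"):
        ins = m.group("ins")
        if len(ins) != 1:
            raise VariantParseError(
                f"insertion token carries one base per ordinal: {token!r}"
            )
        return Variant(pos, VariantKind.INSERTION, ins, int(m.group("idx")), back)
    if m.group("del"):
        return Variant(pos, VariantKind.DELETION, "", 0, back)
    if m.group("base"):
        return Variant(pos, VariantKind.TRANSVERSION, m.group("base"), 0, back)
    return Variant(pos, VariantKind.TRANSITION, "", 0, back)


def format_variant(v: Variant) -> str:
    """Render a :class:`Variant` as its canonical token (inverse of parse)."""
    if v.kind is VariantKind.INSERTION:
        core = f"{v.position}.{v.insertion_index}{v.derived}"
    elif v.kind is VariantKind.DELETION:
        core = f"{v.position}d"
    elif v.kind is VariantKind.TRANSVERSION:
        core = f"{v.position}{v.derived}"
    else:
        core = str(v.position)
    return core + ("!" if v.back_mutation else "")


def parse_variant_tokens(text: str) -> List[Variant]:
    """Parse a whitespace-separated token list.

    Range deletions such as ``290-291d`` are expanded into per-position
    deletion variants; everything else goes through :func:`parse_variant`.
    """
    out: List[Variant] = []
    for token in text.split():
        m = _RANGE_DEL_RE.match(token)
        if m:
            a, b = int(m.group("a")), int(m.group("b"))
            if b < a:
                raise VariantParseError(f"inverted deletion range: {token!r}")
            back = bool(m.group("back"))
            out.extend(Variant(p, VariantKind.DELETION, "", 0, back) for p in range(a, b + 1))
        else:
            out.append(parse_variant(token))
    return out


def format_variants(variants: Iterable[Variant]) -> str:
    """Space-joined canonical tokens in genomic order."""
    ordered = sorted(variants, key=lambda v: (v.position, v.insertion_index, v.kind.value))
    return " ".join(format_variant(v) for v in ordered)
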