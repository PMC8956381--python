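"""Haplogroup tree model and queries.

A haplogroup tree is a rooted tree whose edges carry branch-defining
variants in Phylotree notation. The cumulative profile of a haplogroup is
the accumulation of branch variants along the root-to-node path, with two
path rules:

* back mutation: a ``!``-suffixed token on a branch reverts the site to the
  reference state, removing the matching ancestral variant from the profile
  (the ``!`` token itself is not part of the profile);
* same-position overwrite: a later substitution at an already-mutated
  position replaces the recorded derived state.

The canonical interchange format is a 3-column TSV (``haplogroup``,
``parent``, ``variants``) with space-separated variant tokens.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

from .variants import (
    TRANSITION_PARTNER,
    Variant,
    VariantKind,
    format_variant,
    parse_variant_tokens,
)


class TreeError(ValueError):
    """Structural problem in a haplogroup tree or tree file."""


@dataclass
class HaplogroupNode:
    name: str
    parent: Optional[str]
    branch_variants: List[Variant] = field(default_factory=list)


class HaplogroupTree:
    """Rooted haplogroup tree with cached cumulative profiles."""

    def __init__(self, nodes: Iterable[HaplogroupNode]):
        self.nodes: Dict[str, HaplogroupNode] = {}
        for node in nodes:
            if node.name in self.nodes:
                raise TreeError(f"duplicate haplogroup name: {node.name!r}")
            self.nodes[node.name] = node
        roots = [n.name for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise TreeError(f"expected exactly one root, found {len(roots)}: {roots[:5]}")
        self.root = roots[0]
        self._children: Dict[str, List[str]] = {name: [] for name in self.nodes}
        for node in self.nodes.values():
            if node.parent is None:
                continue
            if node.parent not in self.nodes:
                raise TreeError(f"unknown parent {node.parent!r} of {node.name!r}")
            self._children[node.parent].append(node.name)
        self._depth: Dict[str, int] = {}
        self._assign_depths()
        self._profiles: Dict[str, FrozenSet[Variant]] = {}

    # -- structure -----------------------------------------------------

    def _assign_depths(self) -> None:
        stack = [(self.root, 0)]
        while stack:
            name, d = stack.pop()
            self._depth[name] = d
            stack.extend((c, d + 1) for c in self._children[name])
        if len(self._depth) != len(self.nodes):
            orphans = sorted(set(self.nodes) - set(self._depth))
            raise TreeError(f"cycle or disconnected nodes: {orphans[:5]}")

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def children(self, name: str) -> List[str]:
        self._require(name)
        return list(self._children[name])

    def depth(self, name: str) -> int:
        self._require(name)
        return self._depth[name]

    def path_from_root(self, name: str) -> List[str]:
        self._require(name)
        path = []
        cur: Optional[str] = name
        while cur is not None:
            path.append(cur)
            cur = self.nodes[cur].parent
        return path[::-1]

    def _require(self, name: str) -> None:
        if name not in self.nodes:
            raise TreeError(f"unknown haplogroup: {name!r}")

    # -- profiles ------------------------------------------------------

    def cumulative_profile(self, name: str) -> FrozenSet[Variant]:
        """Set of variants on the root->``name`` path after cancellation."""
        self._require(name)
        if name in self._profiles:
            return self._profiles[name]
        node = self.nodes[name]
        if node.parent is None:
            state: Dict[object, Variant] = {}
        else:
            parent_profile = self.cumulative_profile(node.parent)
            state = {v.site_key: v for v in parent_profile}
        for v in node.branch_variants:
            if v.back_mutation:
                state.pop(v.site_key, None)
            else:
                state[v.site_key] = v
        profile = frozenset(state.values())
        self._profiles[name] = profile
        return profile

    def all_profiles(self) -> Dict[str, FrozenSet[Variant]]:
        return {name: self.cumulative_profile(name) for name in self.nodes}

    # -- queries -------------------------------------------------------

    def mrca(self, names: Iterable[str]) -> str:
        """Most recent common ancestor of a non-empty set of haplogroups."""
        names = list(names)
        if not names:
            raise TreeError("mrca of an empty set")
        for n in names:
            self._require(n)
        paths = [self.path_from_root(n) for n in set(names)]
        shortest = min(len(p) for p in paths)
        mrca = self.root
        for i in range(shortest):
            step = {p[i] for p in paths}
            if len(step) != 1:
                break
            mrca = step.pop()
        return mrca

    def is_ancestor(self, ancestor: str, descendant: str) -> bool:
        return ancestor in self.path_from_root(descendant)

    def sub_haplogroups(self, name: str, level: int = 1, skip_structural: bool = False) -> List[str]:
        """Descendants exactly ``level`` edges below ``name``, natural-sorted.

        With ``skip_structural`` True, nodes that carry no branch variants
        are transparent: they do not consume a level and are themselves
        excluded from the result (their children are counted at the same
        level instead). Both countings are exposed because nomenclature
        trees mix named clades with pass-through structural nodes.
        """
        self._require(name)
        if level < 1:
            raise TreeError("level must be >= 1")
        out: List[str] = []
        stack: List[Tuple[str, int]] = [(c, None) for c in self._children[name]]  # type: ignore[misc]
        stack = [(c, 1) for c in self._children[name]]
        while stack:
            node, eff = stack.pop()
            transparent = skip_structural and not self.nodes[node].branch_variants
            here = eff - 1 if transparent else eff
            if not transparent and here == level:
                out.append(node)
                continue
            if here < level:
                stack.extend((c, here + 1) for c in self._children[node])
        return sorted(out, key=natural_key)

    def discriminating_variants(self, candidates: Iterable[str]) -> Dict[Variant, FrozenSet[str]]:
        """Variants carried by some but not all candidates.

        Maps each such variant to the subset of candidates whose cumulative
        profile contains it.
        """
        names = sorted(set(candidates), key=natural_key)
        if len(names) < 2:
            raise TreeError("need at least two candidates to discriminate")
        profiles = {n: self.cumulative_profile(n) for n in names}
        universe: Set[Variant] = set().union(*profiles.values()) if profiles else set()
        out: Dict[Variant, FrozenSet[str]] = {}
        for v in universe:
            carriers = frozenset(n for n in names if v in profiles[n])
            if 0 < len(carriers) < len(names):
                out[v] = carriers
        return out


# -- natural haplogroup ordering --------------------------------------


_SEGMENT_RE = re.compile(r"(\d+)")


def natural_key(name: str):
    """Sort key with numeric segments compared numerically (H2 < H10)."""
    parts = _SEGMENT_RE.split(name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


# -- sequence reconstruction ------------------------------------------


def apply_variants(
    reference: str,
    variants: Iterable[Variant],
    interval: Optional[Tuple[int, int]] = None,
    warnings: Optional[List[str]] = None,
) -> str:
    """Apply a variant set to (a 1-based inclusive slice of) the reference.

    Substitutions replace the base (transitions via the purine/pyrimidine
    partner of the reference base), deletions drop it, insertions append the
    derived bases after their anchor in ordinal order. Deletion tokens carry
    no expected base, so deletions always apply; a transition at a
    non-ACGT reference base (the placeholder ``N``) cannot be resolved and
    is recorded as a warning instead.
    """
    a, b = interval if interval is not None else (1, len(reference))
    if not (1 <= a <= b <= len(reference)):
        raise ValueError(f"interval ({a}, {b}) outside reference")
    subs: Dict[int, Variant] = {}
    dels: Set[int] = set()
    ins: Dict[int, List[Variant]] = {}
    for v in variants:
        if v.back_mutation:
            raise ValueError(f"unresolved back-mutation token {format_variant(v)!r}")
        if not (1 <= v.position <= len(reference)):
            raise ValueError(f"variant position {v.position} outside reference")
        if v.kind is VariantKind.DELETION:
            dels.add(v.position)
        elif v.kind is VariantKind.INSERTION:
            ins.setdefault(v.position, []).append(v)
        else:
            subs[v.position] = v
    out: List[str] = []
    for pos in range(a, b + 1):
        base = reference[pos - 1]
        if pos in dels:
            base = ""
        elif pos in subs:
            v = subs[pos]
            if v.kind is VariantKind.TRANSVERSION:
                base = v.derived
            elif base in TRANSITION_PARTNER:
                base = TRANSITION_PARTNER[base]
            else:
                if warnings is not None:
                    warnings.append(
                        f"transition at {pos} on non-ACGT reference base {base!r}; left unchanged"
                    )
        out.append(base)
        for v in sorted(ins.get(pos, []), key=lambda x: x.insertion_index):
            out.append(v.derived)
    return "".join(out)


def reference_sequence(
    tree: HaplogroupTree,
    name: str,
    reference: str,
    warnings: Optional[List[str]] = None,
) -> str:
    """Reconstruct the full-length sequence of a haplogroup."""
    return apply_variants(reference, tree.cumulative_profile(name), warnings=warnings)


def haplogroup_fragment(
    tree: HaplogroupTree,
    name: str,
    reference: str,
    interval: Tuple[int, int],
) -> str:
    """Sequence of a haplogroup over a 1-based inclusive rCRS interval."""
    profile = [v for v in tree.cumulative_profile(name) if interval[0] <= v.position <= interval[1]]
    return apply_variants(reference, profile, interval=interval)


# -- I/O ----------------------------------------------------------------


def load_tree(path) -> HaplogroupTree:
    """Load a haplogroup tree from the canonical 3-column TSV."""
    nodes: List[HaplogroupNode] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["haplogroup", "parent", "variants"]
        if [h.strip().lower() for h in header[:3]] != expected:
            raise TreeError(f"expected header {expected}, got {header!r} in {path}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise TreeError(f"{path}:{lineno}: expected at least 2 columns")
            name = fields[0].strip()
            parent = fields[1].strip() or None
            tokens = fields[2].strip() if len(fields) > 2 else ""
            try:
                variants = parse_variant_tokens(tokens)
            except ValueError as exc:
                raise TreeError(f"{path}:{lineno}: {exc}") from exc
            if parent == name:
                raise TreeError(f"{path}:{lineno}: node {name!r} is its own parent")
            nodes.append(HaplogroupNode(name, parent, variants))
    return HaplogroupTree(nodes)


def save_tree(tree: HaplogroupTree, path) -> None:
    """Serialize a tree to the canonical TSV (branch token order preserved)."""
    order = sorted(tree.nodes, key=lambda n: (tree.depth(n), natural_key(n)))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("haplogroup\tparent\tvariants\n")
        for name in order:
            node = tree.nodes[name]
            tokens = " ".join(format_variant(v) for v in node.branch_variants)
            fh.write(f"{name}\t{node.parent or ''}\t{tokens}\n")
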