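"""Haplotype frequency database: construction and lookup.

The database holds three count tables over a sequence corpus:

* ``H(g)`` — how many corpus samples were assigned haplogroup ``g``,
* ``He(g, v)`` — how many of those carried the extra (private) variant ``v``,
* ``Hm(g, v)`` — how many lacked the profile variant ``v``.

It is built by iterative self-classification: the first pass classifies
every corpus sample with identity alone (empty database), each later pass
re-classifies with the previous pass's frequencies and regenerates the
tables from scratch. Every haplogroup tied in a sample's Rank Group 1 is
credited with full weight — multi-haplogroup predictions all count.
Sequences shorter than the minimum length (default 400 bp) are dropped
before construction; identical sequences under different ids are distinct
samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO

from .align import (
    DEFAULT_PARAMS,
    AlignParams,
    Fragment,
    SampleProfile,
    build_sample_profile,
)
from .classify import classify
from .phylotree import HaplogroupTree
from .reference import CR_RANGES, DEFAULT_HOTSPOT_MASK
from .variants import format_variant

DB_SCHEMA_VERSION = 1

#: minimum corpus sequence length (bp); shorter records carry too little
#: information and explode the number of tied predictions
DEFAULT_MIN_LENGTH = 400


class DBError(ValueError):
    pass


@dataclass
class CorpusRecord:
    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def region_class(ranges: Iterable[Tuple[int, int]]) -> str:
    """'CR' when every covered range lies in the control region, else 'genomic'."""
    ranges = list(ranges)
    if ranges and all(
        any(a >= ca and b <= cb for ca, cb in CR_RANGES) for a, b in ranges
    ):
        return "CR"
    return "genomic"


@dataclass
class HaplotypeDB:
    H: Dict[str, int] = field(default_factory=dict)
    He: Dict[Tuple[str, str], int] = field(default_factory=dict)
    Hm: Dict[Tuple[str, str], int] = field(default_factory=dict)
    meta: Dict[str, object] = field(default_factory=dict)

    def h(self, haplogroup: str) -> int:
        return self.H.get(haplogroup, 0)

    def he(self, haplogroup: str, token: str) -> int:
        return self.He.get((haplogroup, token), 0)

    def hm(self, haplogroup: str, token: str) -> int:
        return self.Hm.get((haplogroup, token), 0)

    def lookup(self, haplogroup: str, token: Optional[str], channel: str) -> int:
        if channel == "H":
            return self.h(haplogroup)
        if channel == "He":
            return self.he(haplogroup, token or "")
        if channel == "Hm":
            return self.hm(haplogroup, token or "")
        raise DBError(f"unknown channel {channel!r}")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, HaplotypeDB)
            and self.H == other.H
            and self.He == other.He
            and self.Hm == other.Hm
            and self.meta == other.meta
        )


def filter_corpus(
    records: Sequence[CorpusRecord], min_length: int = DEFAULT_MIN_LENGTH
) -> List[CorpusRecord]:
    """Drop records below the length threshold (boundary inclusive)."""
    return [r for r in records if r.length >= min_length]


def read_corpus_fasta(path) -> List[CorpusRecord]:
    return [
        CorpusRecord(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]


def build_db_from_profiles(
    profiles: Sequence[SampleProfile],
    tree: HaplogroupTree,
    iterations: int = 3,
    credit_groups: int = 1,
    fractional: bool = False,
    credit_policy: str = "all",
    meta: Optional[Dict[str, object]] = None,
) -> HaplotypeDB:
    """Iterative self-classification over pre-called sample profiles.

    ``credit_groups`` widens the credited set from Rank Group 1 to the top-k
    rank groups; ``fractional`` splits each sample's weight evenly over the
    credited haplogroups instead of giving each full weight.
    ``credit_policy`` is ``all`` (every haplogroup in the credited groups)
    or ``top_scored`` (only the maximal-score subset of each sample's Rank
    Group 1 — the policy under which later iterations can actually sharpen
    the tables, since scores then feed back into the credit set).
    """
    if credit_policy not in ("all", "top_scored"):
        raise DBError(f"unknown credit policy {credit_policy!r}")
    if iterations < 1:
        raise DBError("iterations must be >= 1")
    if not profiles:
        raise DBError("empty corpus after filtering")
    db: Optional[HaplotypeDB] = None
    for iteration in range(1, iterations + 1):
        H: Dict[str, int] = {}
        He: Dict[Tuple[str, str], int] = {}
        Hm: Dict[Tuple[str, str], int] = {}
        for profile in profiles:
            result = classify(profile, tree, db, qc=False)
            credited = [
                c for group in result.rank_groups[:credit_groups] for c in group
            ]
            if credit_policy == "top_scored" and credited:
                top = max(c.score for c in credited)
                credited = [c for c in credited if c.score == top]
            weight = 1 / len(credited) if fractional and credited else 1
            for cand in credited:
                g = cand.haplogroup
                H[g] = H.get(g, 0) + weight
                for v in cand.extras:
                    key = (g, format_variant(v))
                    He[key] = He.get(key, 0) + weight
                for v in cand.missing:
                    key = (g, format_variant(v))
                    Hm[key] = Hm.get(key, 0) + weight
        db = HaplotypeDB(H, He, Hm, dict(meta or {}))
        db.meta.update(
            {
                "corpus_size": len(profiles),
                "iterations": iteration,
                "credit_groups": credit_groups,
                "fractional": fractional,
                "credit_policy": credit_policy,
            }
        )
    assert db is not None
    return db


def build_db(
    records: Sequence[CorpusRecord],
    tree: HaplogroupTree,
    reference: str,
    iterations: int = 3,
    min_length: int = DEFAULT_MIN_LENGTH,
    params: AlignParams = DEFAULT_PARAMS,
    hotspot_mask=DEFAULT_HOTSPOT_MASK,
    credit_groups: int = 1,
    fractional: bool = False,
) -> HaplotypeDB:
    """Variant-call a sequence corpus and build the frequency database."""
    retained = filter_corpus(records, min_length)
    if not retained:
        raise DBError("empty corpus after filtering")
    profiles = [
        build_sample_profile(
            [Fragment(rec.id, rec.sequence)],
            reference,
            params,
            hotspot_mask,
            sample_id=rec.id,
        )
        for rec in retained
    ]
    n_cr = sum(1 for p in profiles if region_class(p.ranges) == "CR")
    meta = {
        "min_length": min_length,
        "input_records": len(records),
        "cr_records": n_cr,
        "genomic_records": len(profiles) - n_cr,
    }
    return build_db_from_profiles(
        profiles, tree, iterations, credit_groups, fractional, meta=meta
    )


# -- serialization ------------------------------------------------------
# A database directory holds diff-able, language-neutral text tables:
#   meta.json  — schema version + build metadata
#   h.tsv      — haplogroup <tab> count
#   hv.tsv     — haplogroup <tab> variant <tab> channel(He|Hm) <tab> count


def save_db(db: HaplotypeDB, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {"schema_version": DB_SCHEMA_VERSION, **db.meta}
    (path / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    with open(path / "h.tsv", "w") as fh:
        fh.write("haplogroup\tcount\n")
        for g in sorted(db.H):
            fh.write(f"{g}\t{db.H[g]}\n")
    with open(path / "hv.tsv", "w") as fh:
        fh.write("haplogroup\tvariant\tchannel\tcount\n")
        for channel, table in (("He", db.He), ("Hm", db.Hm)):
            for (g, tok) in sorted(table):
                fh.write(f"{g}\t{tok}\t{channel}\t{table[(g, tok)]}\n")


def _parse_count(text: str):
    value = float(text)
    return int(value) if value.is_integer() else value


def load_db(path) -> HaplotypeDB:
    path = Path(path)
    meta_file = path / "meta.json"
    if not meta_file.exists():
        raise DBError(f"not a haplotype DB directory: {path}")
    meta = json.loads(meta_file.read_text())
    version = meta.pop("schema_version", None)
    if version != DB_SCHEMA_VERSION:
        raise DBError(f"unsupported DB schema version {version!r}")
    db = HaplotypeDB(meta=meta)
    with open(path / "h.tsv") as fh:
        next(fh)
        for line in fh:
            if line.strip():
                g, count = line.rstrip("\n").split("\t")
                db.H[g] = _parse_count(count)
    with open(path / "hv.tsv") as fh:
        next(fh)
        for line in fh:
            if not line.strip():
                continue
            g, tok, channel, count = line.rstrip("\n").split("\t")
            table = db.He if channel == "He" else db.Hm
            table[(g, tok)] = _parse_count(count)
    return db
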