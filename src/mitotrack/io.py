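"""Input/output helpers: FASTA fragment sets, HSD profiles, reports."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import SeqIO

from .align import Fragment, SampleProfile
from .classify import ClassificationResult
from .reference import merge_ranges
from .variants import parse_variant_tokens


def read_fragments_fasta(path, sample_map: Optional[Dict[str, str]] = None) -> Dict[str, List[Fragment]]:
    """Read fragments from a multi-FASTA.

    All records belong to one sample named after the file unless a
    record-id -> sample-id map is given.
    """
    path = Path(path)
    default_sample = path.stem
    out: Dict[str, List[Fragment]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        sample = (sample_map or {}).get(rec.id, default_sample)
        out.setdefault(sample, []).append(Fragment(rec.id, str(rec.seq).upper()))
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def read_sample_map(path) -> Dict[str, str]:
    """TSV of record_id <tab> sample_id."""
    out: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                rec_id, sample_id = line.split("\t")[:2]
                out[rec_id.strip()] = sample_id.strip()
    return out


def _parse_hsd_ranges(text: str) -> List[Tuple[int, int]]:
    ranges: List[Tuple[int, int]] = []
    for chunk in text.replace(",", ";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "-" in chunk:
            a, b = (int(x) for x in chunk.split("-"))
        else:
            a = b = int(chunk)
        if a <= b:
            ranges.append((a, b))
        else:  # origin-spanning range, e.g. 16024-576
            ranges.append((a, 16569))
            ranges.append((1, b))
    return merge_ranges(ranges)


def read_hsd(path) -> List[SampleProfile]:
    """Read HSD-style pre-called profiles.

    Tab-separated: id, covered range(s), haplogroup (ignored, may be ``?``),
    then variant tokens (one per remaining column or space-separated).
    """
    profiles: List[SampleProfile] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lower().startswith(("sampleid\t", "id\t", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least id and range")
            sample_id = fields[0].strip()
            ranges = _parse_hsd_ranges(fields[1])
            tokens = " ".join(fields[3:]) if len(fields) > 3 else ""
            variants = frozenset(parse_variant_tokens(tokens))
            profiles.append(SampleProfile(sample_id, variants, tuple(ranges)))
    return profiles


def write_classification(result: ClassificationResult, out_dir, basename: Optional[str] = None) -> List[Path]:
    """Write a classification report as TSV and JSON; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = basename or result.sample_id
    frame = result.to_frame()
    tsv = out_dir / f"{base}.classification.tsv"
    frame.to_csv(tsv, sep="\t", index=False)
    payload = {
        "sample_id": result.sample_id,
        "qc_flags": result.qc_flags,
        "dropped_ties": result.dropped_ties,
        "candidates": frame.to_dict(orient="records"),
    }
    js = out_dir / f"{base}.classification.json"
    js.write_text(json.dumps(payload, indent=2))
    return [tsv, js]


def write_fasta(sequences: Sequence[Tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
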