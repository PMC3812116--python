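"""FASTA/BED/JSON plumbing around the standard libraries."""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .caller import CrmCandidate
from .scan import SiteMatch

__all__ = [
    "read_fasta",
    "write_fasta",
    "matches_to_bed",
    "candidates_to_bed",
    "match_records",
    "candidate_records",
    "write_json",
]


def read_fasta(path) -> dict[str, str]:
    """Ordered mapping of record id -> uppercase sequence."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def _bed_score(m: SiteMatch) -> int:
    # 12 minus mismatch count when context is present, 0 otherwise
    return 0 if m.flank_mismatches is None else 12 - m.flank_mismatches.count


def matches_to_bed(matches: Sequence[SiteMatch]) -> str:
    """BED6 text; name is the oriented core hexamer."""
    lines = [
        f"{m.seq_id}\t{m.start}\t{m.end}\t{m.core}\t{_bed_score(m)}\t{m.strand}"
        for m in matches
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def candidates_to_bed(candidates: Sequence[CrmCandidate]) -> str:
    lines = [
        f"{c.seq_id}\t{c.start}\t{c.end}\tcrm_{c.architecture}\t"
        f"{c.n_confident or 0}\t."
        for c in candidates
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def match_records(matches: Sequence[SiteMatch]) -> list[dict]:
    out = []
    for m in matches:
        out.append(
            {
                "seq_id": m.seq_id,
                "start": m.start,
                "end": m.end,
                "strand": m.strand,
                "core": m.core,
                "context12": m.context12,
                "mismatch_positions": sorted(m.flank_mismatches.positions)
                if m.flank_mismatches
                else None,
                "mismatch_count": m.mismatch_count,
                "core_status": m.core_status,
            }
        )
    return out


def candidate_records(candidates: Sequence[CrmCandidate]) -> list[dict]:
    from .caller import predict_onset

    out = []
    for c in candidates:
        onset = predict_onset(c)
        rec = {
            "seq_id": c.seq_id,
            "start": c.start,
            "end": c.end,
            "architecture": c.architecture,
            "n_confident": c.n_confident,
            "onset_class": onset.onset_class,
            "stage_label": onset.stage_label,
            "caveat": onset.caveat,
            "sites": match_records(list(c.sites)),
            "spacings_bp": [g for _, _, g, _ in c.spacing.pairs]
            if c.spacing
            else [],
            "helical_offsets_bp": [h for _, _, _, h in c.spacing.pairs]
            if c.spacing
            else [],
        }
        out.append(rec)
    return out


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(o):
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
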