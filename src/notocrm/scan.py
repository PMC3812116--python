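"""Both-strand degenerate-core scanning, 12-bp context annotation and spacing.

Coordinates are 0-based half-open on the forward strand throughout; minus
strand hits keep forward coordinates but report core/context strings in site
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .motif import (
    CORE_OFFSET_IN_FRAME,
    CORE_PATTERN,
    EXTENDED_CONSENSUS,
    IUPAC_SETS,
    IupacPattern,
    MismatchReport,
    SiteCatalog,
    consensus_mismatches,
    revcomp,
)

__all__ = ["SiteMatch", "SpacingReport", "scan", "annotate", "spacing",
           "HELICAL_PERIOD_BP", "scan_and_annotate"]

#: one turn of B-form DNA
HELICAL_PERIOD_BP = 10.5

# bases of context flanking the core in the 12-bp frame, in site orientation
_FLANK5 = CORE_OFFSET_IN_FRAME  # 4
_FLANK3 = 12 - CORE_OFFSET_IN_FRAME - 6  # 2


@dataclass(frozen=True)
class SiteMatch:
    seq_id: str
    start: int  # 0-based inclusive, forward coordinates
    end: int  # exclusive; end - start == core length
    strand: str  # '+' or '-'
    core: str  # oriented core sequence
    context12: Optional[str] = None  # oriented 12-bp frame, None near edges
    flank_mismatches: Optional[MismatchReport] = None
    core_status: Optional[str] = None

    @property
    def mismatch_count(self) -> Optional[int]:
        return None if self.flank_mismatches is None else self.flank_mismatches.count


@dataclass(frozen=True)
class SpacingReport:
    """Edge-to-edge gaps between consecutive site matches."""

    pairs: tuple[tuple[SiteMatch, SiteMatch, int, float], ...]
    helical_period: float = HELICAL_PERIOD_BP


def scan(
    seq: str,
    seq_id: str = "seq",
    pattern: IupacPattern = CORE_PATTERN,
    strands: str = "both",
) -> list[SiteMatch]:
    """All offsets where ``pattern`` matches ``seq``, optionally on both strands.

    Overlapping matches are all reported.  Output is sorted by start, then
    '+' before '-'.
    """
    if strands not in ("forward", "both"):
        raise ValueError(f"strands must be 'forward' or 'both', got {strands!r}")
    w = len(pattern)
    s = seq.upper()
    # precomputed base sets; input 'N' is absent from every set, so masked
    # bases can never match (same policy as iupac_matches)
    fwd_sets = [IUPAC_SETS[c] for c in pattern.symbols]
    rc_sets = [IUPAC_SETS[c] for c in pattern.reverse_complement().symbols]
    hits: list[SiteMatch] = []
    for i in range(len(s) - w + 1):
        if all(s[i + j] in fwd_sets[j] for j in range(w)):
            hits.append(SiteMatch(seq_id, i, i + w, "+", s[i : i + w]))
        if strands == "both" and all(s[i + j] in rc_sets[j] for j in range(w)):
            hits.append(SiteMatch(seq_id, i, i + w, "-", revcomp(s[i : i + w])))
    hits.sort(key=lambda m: (m.start, m.strand))
    return hits


def annotate(
    match: SiteMatch, seq: str, catalog: Optional[SiteCatalog] = None
) -> SiteMatch:
    """Attach the oriented 12-bp context, flank mismatches and catalog status.

    Context (and the mismatch report) is absent when the 12-bp window
    overruns either end of the sequence; such matches keep the bare core hit
    and are treated as low-confidence downstream.
    """
    s = seq.upper()
    if not (0 <= match.start < match.end <= len(s)):
        raise IndexError(
            f"match {match.start}-{match.end} outside sequence of length {len(s)}"
        )
    if s[match.start : match.end] != (
        match.core if match.strand == "+" else revcomp(match.core)
    ):
        raise ValueError("match core does not correspond to the sequence")
    if match.strand == "+":
        lo, hi = match.start - _FLANK5, match.end + _FLANK3
    else:  # site 5' flank lies 3' on the forward strand
        lo, hi = match.start - _FLANK3, match.end + _FLANK5
    context: Optional[str] = None
    mm: Optional[MismatchReport] = None
    if 0 <= lo and hi <= len(s):
        window = s[lo:hi]
        context = window if match.strand == "+" else revcomp(window)
        mm = consensus_mismatches(context, EXTENDED_CONSENSUS)
    status = catalog.status_of(match.core) if catalog is not None else None
    return replace(
        match, context12=context, flank_mismatches=mm, core_status=status
    )


def scan_and_annotate(
    seq: str,
    seq_id: str = "seq",
    catalog: Optional[SiteCatalog] = None,
    pattern: IupacPattern = CORE_PATTERN,
    strands: str = "both",
) -> list[SiteMatch]:
    return [annotate(m, seq, catalog) for m in scan(seq, seq_id, pattern, strands)]


def spacing(matches: Sequence[SiteMatch]) -> SpacingReport:
    """Gaps between consecutive matches, edge-to-edge, with helical offsets."""
    ids = {m.seq_id for m in matches}
    if len(ids) > 1:
        raise ValueError(f"matches span multiple sequences: {sorted(ids)}")
    starts = [m.start for m in matches]
    if starts != sorted(starts):
        raise ValueError("matches must be sorted by start")
    pairs = []
    for up, down in zip(matches, matches[1:]):
        gap = down.start - up.end
        pairs.append((up, down, gap, gap % HELICAL_PERIOD_BP))
    return SpacingReport(pairs=tuple(pairs))
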