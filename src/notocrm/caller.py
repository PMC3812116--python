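"""CRM-candidate calling, architecture classification and onset prediction.

Architecture maps deterministically onto temporal onset class: two or more
confident sites -> early (110-cell to early gastrula), exactly one -> middle
(late gastrula / neural plate), none -> late-or-indirect (neurula; relay
candidate).  A zero-site call is a conditional prediction, valid only if the
interval is independently known to be active; reports carry that caveat.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .motif import SiteCatalog
from .scan import SiteMatch, SpacingReport, spacing

__all__ = [
    "CrmCandidate",
    "OnsetPrediction",
    "DEFAULT_WINDOW_BP",
    "DEFAULT_MAX_FLANK_MM",
    "DEFAULT_WHITELIST",
    "ZERO_SITE_CAVEAT",
    "is_confident",
    "call_candidates",
    "candidate_from_interval",
    "classify",
    "predict_onset",
]

# Defaults: 300 bp is the upper end of the observed minimal-CRM size range
# (65 to ~300 bp); 4 is the maximum flank-mismatch count observed among the
# 24 catalogued functional sites; the whitelist restricts to the 9 cores
# with demonstrated requirement.
DEFAULT_WINDOW_BP = 300
DEFAULT_MAX_FLANK_MM = 4
DEFAULT_WHITELIST = "required_only"

ZERO_SITE_CAVEAT = (
    "late_or_indirect is a conditional prediction: it applies only if this "
    "interval is independently known to be notochord-active (relay candidate)"
)

_STAGE_LABELS = {
    "early": "110-cell–early gastrula",
    "middle": "late gastrula/neural plate",
    "late_or_indirect": "neurula; relay candidate",
}

_ARCH_TO_ONSET = {
    "multiple": "early",
    "single": "middle",
    "none": "late_or_indirect",
}


@dataclass(frozen=True)
class CrmCandidate:
    seq_id: str
    start: int
    end: int
    sites: tuple[SiteMatch, ...]
    n_confident: Optional[int] = None
    architecture: Optional[str] = None  # multiple | single | none
    spacing: Optional[SpacingReport] = None


@dataclass(frozen=True)
class OnsetPrediction:
    onset_class: str  # early | middle | late_or_indirect
    stage_label: str
    basis: int  # n_confident
    caveat: Optional[str] = None


def is_confident(
    site: SiteMatch,
    catalog: SiteCatalog,
    max_flank_mm: int = DEFAULT_MAX_FLANK_MM,
    core_whitelist: str = DEFAULT_WHITELIST,
) -> bool:
    """Whitelisted core with full context and few flank mismatches.

    Sites lacking a 12-bp context (sequence-edge hits) never count.
    """
    if site.core.upper() not in catalog.whitelist(core_whitelist):
        return False
    if site.flank_mismatches is None:
        return False
    return site.flank_mismatches.count <= max_flank_mm


def call_candidates(
    matches: Sequence[SiteMatch],
    catalog: SiteCatalog,
    window: int = DEFAULT_WINDOW_BP,
    min_sites: int = 1,
    max_flank_mm: int = DEFAULT_MAX_FLANK_MM,
    core_whitelist: str = DEFAULT_WHITELIST,
) -> list[CrmCandidate]:
    """Cluster confident sites into candidate intervals.

    Maximal runs of confident sites in which consecutive sites are at most
    ``window`` bp apart (edge-to-edge) form one candidate spanning first
    site start to last site end.  Non-confident matches falling inside the
    interval are attached to the candidate's site list but do not extend it.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    out: list[CrmCandidate] = []
    by_seq: dict[str, list[SiteMatch]] = {}
    for m in matches:
        by_seq.setdefault(m.seq_id, []).append(m)
    for seq_id, ms in by_seq.items():
        ms = sorted(ms, key=lambda m: (m.start, m.strand))
        confident = [m for m in ms if is_confident(m, catalog, max_flank_mm, core_whitelist)]
        runs: list[list[SiteMatch]] = []
        for m in confident:
            if runs and m.start - runs[-1][-1].end <= window:
                runs[-1].append(m)
            else:
                runs.append([m])
        for run in runs:
            if len(run) < min_sites:
                continue
            start, end = run[0].start, run[-1].end
            inside = tuple(m for m in ms if m.start >= start and m.end <= end)
            cand = CrmCandidate(seq_id=seq_id, start=start, end=end, sites=inside)
            out.append(classify(cand, catalog, max_flank_mm, core_whitelist))
    out.sort(key=lambda c: (c.seq_id, c.start))
    return out


def candidate_from_interval(
    seq_id: str,
    start: int,
    end: int,
    matches: Sequence[SiteMatch],
    catalog: SiteCatalog,
    max_flank_mm: int = DEFAULT_MAX_FLANK_MM,
    core_whitelist: str = DEFAULT_WHITELIST,
) -> CrmCandidate:
    """Annotate a user-provided interval, even when it contains no site."""
    if end <= start:
        raise ValueError("interval end must exceed start")
    inside = tuple(
        m
        for m in sorted(matches, key=lambda m: (m.start, m.strand))
        if m.seq_id == seq_id and m.start >= start and m.end <= end
    )
    cand = CrmCandidate(seq_id=seq_id, start=start, end=end, sites=inside)
    return classify(cand, catalog, max_flank_mm, core_whitelist)


def classify(
    candidate: CrmCandidate,
    catalog: SiteCatalog,
    max_flank_mm: int = DEFAULT_MAX_FLANK_MM,
    core_whitelist: str = DEFAULT_WHITELIST,
) -> CrmCandidate:
    """Count confident sites and set the architecture class."""
    conf = [
        m
        for m in candidate.sites
        if is_confident(m, catalog, max_flank_mm, core_whitelist)
    ]
    n = len(conf)
    arch = "multiple" if n >= 2 else ("single" if n == 1 else "none")
    sp = spacing(sorted(conf, key=lambda m: m.start)) if len(conf) >= 2 else None
    return replace(candidate, n_confident=n, architecture=arch, spacing=sp)


def predict_onset(candidate: CrmCandidate) -> OnsetPrediction:
    """Deterministic architecture -> onset-class mapping."""
    if candidate.architecture is None or candidate.n_confident is None:
        raise ValueError("candidate must be classified before onset prediction")
    onset = _ARCH_TO_ONSET[candidate.architecture]
    return OnsetPrediction(
        onset_class=onset,
        stage_label=_STAGE_LABELS[onset],
        basis=candidate.n_confident,
        caveat=ZERO_SITE_CAVEAT if candidate.architecture == "none" else None,
    )
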