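"""In-silico site ablation and predicted architecture/onset shifts.

The packaged ablation scheme replaces the CAC half of a TNNCAC core with TCT
(e.g. TGGCAC -> TGGTCT), the mutation style found to be most effective in
the source assays; arbitrary same-length replacements are supported for
everything else (e.g. homeodomain AATTAA -> TTTTGC).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .caller import (
    CrmCandidate,
    DEFAULT_MAX_FLANK_MM,
    DEFAULT_WHITELIST,
    classify,
)
from .motif import CORE_PATTERN, IupacPattern, SiteCatalog, pattern_match, revcomp
from .scan import SiteMatch

__all__ = ["MutationSpec", "EffectPrediction", "ablate", "ablate_core",
           "predict_effect", "PARTIAL_REDUNDANCY_CAVEAT"]

CAC_TO_TCT = "cac_to_tct"

PARTIAL_REDUNDANCY_CAVEAT = (
    "graded residual activity after partial ablation of cooperative sites "
    "is not modeled; the discrete class assumes full synergy"
)


@dataclass(frozen=True)
class MutationSpec:
    """One mutation: a scanner hit or an explicit interval, plus a scheme."""

    target: Union[SiteMatch, tuple[int, int]]
    scheme: str = CAC_TO_TCT  # or a same-length replacement string
    strand: str = "+"  # orientation for interval targets

    def interval(self) -> tuple[int, int]:
        if isinstance(self.target, SiteMatch):
            return self.target.start, self.target.end
        return self.target

    def orientation(self) -> str:
        if isinstance(self.target, SiteMatch):
            return self.target.strand
        return self.strand


_ABLATED_PATTERN = IupacPattern("TNNTCT")


def ablate_core(core: str) -> str:
    """TNNCAC -> TNNTCT (site orientation); already-ablated input is a no-op."""
    c = core.upper()
    if pattern_match(c, _ABLATED_PATTERN):  # fixed point: idempotent reapply
        return c
    if not pattern_match(c, CORE_PATTERN):
        raise ValueError(f"{core!r} does not match the core pattern TNNCAC")
    return c[:3] + "TCT"


def ablate(seq: str, spec: MutationSpec) -> str:
    """Apply one mutation; sequence length is preserved."""
    start, end = spec.interval()
    if not (0 <= start < end <= len(seq)):
        raise IndexError(f"target {start}-{end} outside sequence")
    fwd = seq.upper()[start:end]
    oriented = fwd if spec.orientation() == "+" else revcomp(fwd)
    if spec.scheme == CAC_TO_TCT:
        mutated_oriented = ablate_core(oriented)
    else:
        if len(spec.scheme) != len(oriented):
            raise ValueError("replacement must preserve length")
        mutated_oriented = spec.scheme.upper()
    mutated_fwd = (
        mutated_oriented if spec.orientation() == "+" else revcomp(mutated_oriented)
    )
    return seq[:start] + mutated_fwd + seq[end:]


@dataclass(frozen=True)
class EffectPrediction:
    predicted_architecture: str  # multiple | single | none
    predicted_activity: str  # active_early | active_middle | inactive
    n_confident_before: int
    n_confident_after: int
    caveat: Optional[str] = None


def predict_effect(
    candidate: CrmCandidate,
    ablations: Sequence[MutationSpec],
    catalog: SiteCatalog,
    max_flank_mm: int = DEFAULT_MAX_FLANK_MM,
    core_whitelist: str = DEFAULT_WHITELIST,
) -> EffectPrediction:
    """Re-classify a candidate after removing the ablated sites.

    On a direct-target candidate (one or more confident sites), losing every
    confident site predicts inactivity; dropping from multiple to a single
    remaining site predicts a delayed (middle) onset.
    """
    if candidate.architecture is None:
        raise ValueError("candidate must be classified")
    ab_keys = set()
    for spec in ablations:
        start, end = spec.interval()
        if not (start >= candidate.start and end <= candidate.end):
            raise IndexError(
                f"ablation {start}-{end} outside candidate "
                f"{candidate.start}-{candidate.end}"
            )
        ab_keys.add((start, end))
    remaining = tuple(
        m for m in candidate.sites if (m.start, m.end) not in ab_keys
    )
    after = classify(
        CrmCandidate(
            seq_id=candidate.seq_id,
            start=candidate.start,
            end=candidate.end,
            sites=remaining,
        ),
        catalog,
        max_flank_mm,
        core_whitelist,
    )
    was_direct = (candidate.n_confident or 0) >= 1
    if after.architecture == "multiple":
        activity = "active_early"
    elif after.architecture == "single":
        activity = "active_middle"
    else:
        activity = "inactive" if was_direct else "active_late_or_indirect"
    caveat = (
        PARTIAL_REDUNDANCY_CAVEAT
        if candidate.architecture == "multiple" and ablations
        else None
    )
    return EffectPrediction(
        predicted_architecture=after.architecture,
        predicted_activity=activity,
        n_confident_before=candidate.n_confident or 0,
        n_confident_after=after.n_confident or 0,
        caveat=caveat,
    )
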