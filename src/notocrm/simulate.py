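"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: i.i.d. backgrounds
of chosen GC content, loci with planted site architectures (multiple /
single / zero confident sites), staged embryo-staining count tables driven
by class-specific logistic activation, and ChIP-qPCR runs with planted
amplification efficiency and IP enrichment.  Every generator is a pure
function of its parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .assays import QpcrRun, StainingTable
from .caller import DEFAULT_MAX_FLANK_MM, DEFAULT_WHITELIST
from .motif import (
    CORE_OFFSET_IN_FRAME,
    CORE_PATTERN,
    SiteCatalog,
    IUPAC_SETS,
    load_catalog,
    pattern_match,
    revcomp,
)
from .scan import scan_and_annotate
from . import caller

__all__ = [
    "PlantSpec",
    "PlantedSite",
    "SyntheticTruth",
    "ActivationParams",
    "DEFAULT_STAGES",
    "CLASS_SPECS",
    "gen_background",
    "plant_crm",
    "gen_genome",
    "gen_embryo_counts",
    "expected_onset_stage",
    "gen_qpcr",
]

DEFAULT_STAGES = (
    "110-cell",
    "early_gastrula",
    "mid_gastrula",
    "late_gastrula",
    "neural_plate",
    "neurula",
    "tailbud",
)

_CLASS_TO_NSITES = {"early": 2, "middle": 1, "late_or_indirect": 0}


@dataclass(frozen=True)
class PlantSpec:
    """Ordered cores (hexamer, orientation, flank fidelity) plus spacings.

    ``spacings`` are edge-to-edge gaps in bp between consecutive cores.
    Fidelity is one of exact_consensus / paper_site / random.
    """

    cores: tuple[tuple[str, str, str], ...]
    spacings: tuple[int, ...] = ()
    intended_class: str = "late_or_indirect"

    def __post_init__(self) -> None:
        if len(self.spacings) != max(len(self.cores) - 1, 0):
            raise ValueError("need exactly len(cores)-1 spacings")
        if self.intended_class not in _CLASS_TO_NSITES:
            raise ValueError(f"bad class {self.intended_class!r}")
        want = _CLASS_TO_NSITES[self.intended_class]
        n = len(self.cores)
        ok = n >= 2 if want == 2 else n == want
        if not ok:
            raise ValueError(
                f"{n} cores inconsistent with class {self.intended_class!r}"
            )
        for hexamer, strand, fidelity in self.cores:
            if not pattern_match(hexamer, CORE_PATTERN):
                raise ValueError(f"{hexamer!r} does not match the core pattern")
            if strand not in "+-":
                raise ValueError(f"bad orientation {strand!r}")
            if fidelity not in ("exact_consensus", "paper_site", "random"):
                raise ValueError(f"bad fidelity {fidelity!r}")


# default architecture exemplars: a two-site arrangement with the 35-bp
# spacing, a lone single-site core, and a site-free locus
CLASS_SPECS = {
    "early": PlantSpec(
        cores=(("TAACAC", "+", "paper_site"), ("TCACAC", "+", "paper_site")),
        spacings=(35,),
        intended_class="early",
    ),
    "middle": PlantSpec(
        cores=(("TGACAC", "+", "paper_site"),),
        intended_class="middle",
    ),
    "late_or_indirect": PlantSpec(cores=(), intended_class="late_or_indirect"),
}


@dataclass(frozen=True)
class PlantedSite:
    core_start: int  # forward 0-based start of the 6-bp core
    core_end: int
    strand: str
    hexamer: str
    context12: str  # oriented 12-mer as written


@dataclass(frozen=True)
class SyntheticTruth:
    locus_id: str
    intended_class: str
    interval: tuple[int, int]  # planted span, 0-based half-open; (0,0) if empty
    sites: tuple[PlantedSite, ...]
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def gen_background(length: int, gc: float, seed: int) -> str:
    """i.i.d. sequence with P(G)=P(C)=gc/2; byte-reproducible given seed."""
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    if length < 0:
        raise ValueError("length must be non-negative")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def _consensus_frame(core: str, rng: np.random.Generator) -> str:
    """A 12-mer whose flanks satisfy RWWNTNRCACYT around the given core."""
    pick = lambda code: rng.choice(sorted(IUPAC_SETS[code]))
    return (
        pick("R") + pick("W") + pick("W") + pick("N") + core + pick("Y") + "T"
    )


def _site_frame(
    core: str, fidelity: str, catalog: SiteCatalog, rng: np.random.Generator
) -> str:
    core = core.upper()
    if fidelity == "paper_site":
        options = catalog.sites_for_core(core)
        if options:
            idx = int(rng.integers(len(options)))
            return options[idx].sequence12.upper()
        fidelity = "exact_consensus"
    if fidelity == "exact_consensus":
        return _consensus_frame(core, rng)
    flank = lambda n: "".join(rng.choice(list("ACGT"), size=n))
    return flank(4) + core + flank(2)


def plant_crm(
    background: str,
    spec: PlantSpec,
    offset: int,
    seed: int,
    catalog: Optional[SiteCatalog] = None,
    locus_id: str = "locus",
) -> tuple[str, SyntheticTruth]:
    """Write the spec's sites into ``background`` starting at ``offset``.

    Cores land at deterministic forward offsets: the first core starts at
    ``offset + 4`` and consecutive cores are separated edge-to-edge by the
    spec's spacings, so the scanner's spacing report reproduces them
    exactly.  Minus-strand sites are written as the reverse complement of
    their oriented 12-mer.
    """
    catalog = catalog or load_catalog()
    rng = np.random.default_rng(seed)
    if not spec.cores:
        return background, SyntheticTruth(
            locus_id, spec.intended_class, (0, 0), (), seed
        )
    seq = list(background)
    planted: list[PlantedSite] = []
    core_start = offset + CORE_OFFSET_IN_FRAME
    span_lo, span_hi = len(background), 0
    for i, (hexamer, strand, fidelity) in enumerate(spec.cores):
        frame = _site_frame(hexamer, fidelity, catalog, rng)
        fwd = frame if strand == "+" else revcomp(frame)
        # forward offset of the 12-bp window so the core starts at core_start
        win_lo = core_start - (CORE_OFFSET_IN_FRAME if strand == "+" else 2)
        win_hi = win_lo + 12
        if win_lo < 0 or win_hi > len(seq):
            raise IndexError(
                f"planted site {i} ({win_lo}-{win_hi}) overflows the background"
            )
        seq[win_lo:win_hi] = fwd
        planted.append(
            PlantedSite(core_start, core_start + 6, strand, hexamer.upper(), frame)
        )
        span_lo, span_hi = min(span_lo, win_lo), max(span_hi, win_hi)
        if i < len(spec.spacings):
            core_start += 6 + spec.spacings[i]
    truth = SyntheticTruth(
        locus_id, spec.intended_class, (span_lo, span_hi), tuple(planted), seed
    )
    return "".join(seq), truth


def _confident_positions(
    seq: str, catalog: SiteCatalog, max_flank_mm: int, whitelist: str
) -> set[tuple[int, str]]:
    return {
        (m.start, m.strand)
        for m in scan_and_annotate(seq, "x", catalog)
        if caller.is_confident(m, catalog, max_flank_mm, whitelist)
    }


def gen_genome(
    n_loci: int,
    class_mix: Sequence[float],
    length: int = 600,
    gc: float = 0.4,
    seed: int = 0,
    scrub: bool = True,
    catalog: Optional[SiteCatalog] = None,
    max_flank_mm: int = DEFAULT_MAX_FLANK_MM,
    core_whitelist: str = DEFAULT_WHITELIST,
    max_retries: int = 1000,
) -> tuple[dict[str, str], list[SyntheticTruth]]:
    """A multi-locus synthetic genome with per-locus planted architectures.

    ``class_mix`` gives fractions of early / middle / late_or_indirect loci.
    With ``scrub=True`` each locus background is rejection-sampled until the
    only confident sites found anywhere in the planted locus are exactly the
    planted ones, guaranteeing exact class recovery by the classifier.
    """
    if abs(sum(class_mix) - 1.0) > 1e-9 or len(class_mix) != 3:
        raise ValueError("class_mix must be 3 fractions summing to 1")
    catalog = catalog or load_catalog()
    counts = [int(np.floor(f * n_loci)) for f in class_mix]
    # largest-remainder rounding
    rem = n_loci - sum(counts)
    order = np.argsort([-(f * n_loci - c) for f, c in zip(class_mix, counts)])
    for k in range(rem):
        counts[order[k % 3]] += 1
    classes = (
        ["early"] * counts[0]
        + ["middle"] * counts[1]
        + ["late_or_indirect"] * counts[2]
    )
    seeds = np.random.SeedSequence(seed).spawn(n_loci)
    genome: dict[str, str] = {}
    truths: list[SyntheticTruth] = []
    for i, (cls, ss) in enumerate(zip(classes, seeds)):
        locus_id = f"locus_{i:03d}_{cls}"
        spec = CLASS_SPECS[cls]
        span = 12 + sum(6 + g for g in spec.spacings) if spec.cores else 0
        if span > length:
            raise ValueError(f"locus length {length} too short for spec span {span}")
        offset = (length - span) // 2
        attempt_seeds = ss.spawn(max_retries)
        seq = truth = None
        for att in attempt_seeds:
            child = np.random.default_rng(att)
            bg_seed = int(child.integers(2**63))
            plant_seed = int(child.integers(2**63))
            bg = gen_background(length, gc, bg_seed)
            cand_seq, cand_truth = plant_crm(
                bg, spec, offset, plant_seed, catalog, locus_id
            )
            if not scrub:
                seq, truth = cand_seq, cand_truth
                break
            found = _confident_positions(
                cand_seq, catalog, max_flank_mm, core_whitelist
            )
            want = {(s.core_start, s.strand) for s in cand_truth.sites}
            if found == want:
                seq, truth = cand_seq, cand_truth
                break
        if seq is None:
            raise RuntimeError(
                f"scrub failed for {locus_id} after {max_retries} retries "
                f"(length={length}, gc={gc}); try a shorter locus or lower GC"
            )
        genome[locus_id] = seq
        truths.append(truth)
    return genome, truths


@dataclass(frozen=True)
class ActivationParams:
    """Logistic activation of notochord staining across ordered stages."""

    midpoints: dict = field(
        default_factory=lambda: {
            "early": "early_gastrula",
            "middle": "late_gastrula",
            "late_or_indirect": "neurula",
        }
    )
    steepness: float = 8.0
    p_max: float = 0.8
    p_base: float = 0.01
    notochord_only_share: float = 0.7


def _activation_curve(
    intended_class: str, stages: Sequence[str], params: ActivationParams
) -> np.ndarray:
    mid_stage = params.midpoints[intended_class]
    if mid_stage not in stages:
        raise ValueError(f"midpoint stage {mid_stage!r} not in stage list")
    m = list(stages).index(mid_stage)
    i = np.arange(len(stages), dtype=float)
    logistic = 1.0 / (1.0 + np.exp(-params.steepness * (i - (m - 0.5))))
    return params.p_base + (params.p_max - params.p_base) * logistic


def expected_onset_stage(
    intended_class: str,
    stages: Sequence[str] = DEFAULT_STAGES,
    params: Optional[ActivationParams] = None,
    threshold: float = 0.10,
) -> Optional[str]:
    """Stage where the configured activation curve first reaches threshold."""
    params = params or ActivationParams()
    p = _activation_curve(intended_class, stages, params)
    hits = np.nonzero(p >= threshold)[0]
    return stages[int(hits[0])] if hits.size else None


def gen_embryo_counts(
    intended_class: str,
    stages: Sequence[str] = DEFAULT_STAGES,
    n_per_stage: int = 100,
    activation_params: Optional[ActivationParams] = None,
    seed: int = 0,
    construct: str = "synthetic",
) -> StainingTable:
    """Binomial staged staining counts under a class-specific logistic curve."""
    if n_per_stage <= 0:
        raise ValueError("n_per_stage must be positive")
    params = activation_params or ActivationParams()
    rng = np.random.default_rng(seed)
    p = _activation_curve(intended_class, stages, params)
    rows = []
    for stage, pi in zip(stages, p):
        n_noto = int(rng.binomial(n_per_stage, pi))
        n_only = int(rng.binomial(n_noto, params.notochord_only_share)) if n_noto else 0
        rows += [
            (construct, stage, "notochord_only", n_only),
            (construct, stage, "notochord_plus_other", n_noto - n_only),
            (construct, stage, "other_only", n_per_stage - n_noto),
        ]
    df = pd.DataFrame(rows, columns=["construct", "stage", "category", "count"])
    return StainingTable(df, tuple(stages))


def gen_qpcr(
    enrichment_fold: float = 8.0,
    efficiency: float = 1.0,
    replicates: int = 3,
    seed: int = 0,
    sigma_ct: float = 0.15,
    start_mass: float = 20.0,
    dilutions: Sequence[float] = (5.0, 50.0, 500.0, 5000.0),
    input_fraction: float = 0.01,
    base_percent_input: float = 0.5,
    intercept: float = 22.0,
    input_mass: float = 2.0,
) -> QpcrRun:
    """A qPCR run with planted amplification efficiency and IP enrichment.

    Standards follow Ct = intercept + slope*log10(mass) with
    slope = -1/log10(1+efficiency); IgG percent input is
    ``base_percent_input`` and the antibody IP is ``enrichment_fold`` times
    that.  Gaussian noise with sd ``sigma_ct`` is added to every Ct.
    """
    if enrichment_fold <= 0:
        raise ValueError("enrichment_fold must be positive")
    if not 0 < efficiency <= 1:
        raise ValueError("efficiency must be in (0, 1]")
    rng = np.random.default_rng(seed)
    slope = -1.0 / np.log10(1.0 + efficiency)

    def ct_of(mass: float) -> float:
        return intercept + slope * np.log10(mass) + rng.normal(0.0, sigma_ct)

    standards = []
    for d in dilutions:
        for _ in range(2):  # duplicates per dilution level
            standards.append((float(d), float(ct_of(start_mass / d))))
    chromatin = input_mass / input_fraction
    q_igg = chromatin * base_percent_input / 100.0
    q_bra = q_igg * enrichment_fold
    rows = []
    for r in range(1, replicates + 1):
        rows += [
            ("input", r, float(ct_of(input_mass))),
            ("igg", r, float(ct_of(q_igg))),
            ("bra", r, float(ct_of(q_bra))),
        ]
    samples = pd.DataFrame(rows, columns=["label", "replicate", "ct"])
    return QpcrRun(
        standards=standards,
        samples=samples,
        start_mass=start_mass,
        input_fraction=input_fraction,
    )
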