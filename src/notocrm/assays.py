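"""Quantification arithmetic for reporter-staining tables and ChIP-qPCR.

Staining tables count embryos per construct/stage in tissue-pattern
categories; fractions are of total stained embryos.  qPCR quantities are
interpolated from a genomic-DNA standard curve (Ct vs log10 mass), not via
delta-delta-Ct; percent input adjusts for the chromatin fraction used as
input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StainingTable",
    "QpcrRun",
    "StandardCurve",
    "ChipResult",
    "NOTOCHORD_CATEGORIES",
    "DEFAULT_ONSET_THRESHOLD",
    "staining_fractions",
    "onset_from_timecourse",
    "compare_proportions",
    "standard_curve",
    "chip_enrichment",
]

#: tissue-pattern categories; the first two count as notochord-positive
NOTOCHORD_CATEGORIES = ("notochord_only", "notochord_plus_other", "other_only")

#: first-detection convention: ~10% of embryos stained in notochord
DEFAULT_ONSET_THRESHOLD = 0.10


@dataclass
class StainingTable:
    """Long-format embryo counts: construct, stage, category, count."""

    data: pd.DataFrame
    stage_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        required = {"construct", "stage", "category", "count"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"staining table missing columns {sorted(missing)}")
        if (self.data["count"] < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.stage_order:
            self.stage_order = tuple(pd.unique(self.data["stage"]))

    @classmethod
    def read_tsv(cls, path, stage_order: Sequence[str] = ()) -> "StainingTable":
        return cls(pd.read_csv(path, sep="\t"), tuple(stage_order))

    def write_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def staining_fractions(table: StainingTable) -> pd.DataFrame:
    """Category fractions of total stained embryos per construct/stage.

    Groups with zero total are flagged ``undefined`` and carry NaN
    fractions rather than raising.
    """
    df = table.data
    totals = df.groupby(["construct", "stage"])["count"].transform("sum")
    out = df.copy()
    with np.errstate(invalid="ignore"):
        out["fraction"] = np.where(totals > 0, df["count"] / totals.replace(0, np.nan), np.nan)
    out["undefined"] = totals == 0
    return out


def onset_from_timecourse(
    table: StainingTable,
    threshold: float = DEFAULT_ONSET_THRESHOLD,
    construct: Optional[str] = None,
) -> Optional[str]:
    """Earliest stage with notochord-positive fraction >= threshold, or None.

    The notochord-positive fraction at a stage is the share of embryos in
    the notochord_only and notochord_plus_other categories among all
    embryos counted at that stage.
    """
    df = table.data
    if construct is not None:
        df = df[df["construct"] == construct]
    if df.empty:
        raise ValueError("empty staining table")
    noto = ("notochord_only", "notochord_plus_other")
    for stage in table.stage_order:
        sub = df[df["stage"] == stage]
        if sub.empty:
            continue
        total = sub["count"].sum()
        if total == 0:
            continue
        frac = sub.loc[sub["category"].isin(noto), "count"].sum() / total
        if (threshold == 0 and frac > 0) or (threshold > 0 and frac >= threshold):
            return stage
    return None


def compare_proportions(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Two-sided Fisher exact p-value for equality of two proportions k/n."""
    for k, n in (a, b):
        if not (0 <= k <= n) or n <= 0:
            raise ValueError(f"invalid counts k={k}, n={n}")
    table = [[a[0], a[1] - a[0]], [b[0], b[1] - b[0]]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


@dataclass(frozen=True)
class StandardCurve:
    slope: float
    intercept: float
    efficiency: float
    r_squared: float

    def quantity(self, ct: float) -> float:
        """Interpolate input mass (same units as the standards) from a Ct."""
        return float(10 ** ((ct - self.intercept) / self.slope))


@dataclass
class QpcrRun:
    """Standards plus sample Cts for one ChIP-qPCR experiment.

    ``standards``: (dilution_factor, ct) pairs from a genomic-DNA series
    starting at ``start_mass`` (e.g. 5-, 50-, 500-, 5000-fold from 20 ng).
    ``samples``: columns label (e.g. 'bra', 'igg', 'input'), replicate, ct.
    ``input_fraction``: fraction of chromatin used as the input sample.
    """

    standards: list[tuple[float, float]]
    samples: pd.DataFrame
    start_mass: float = 20.0
    input_fraction: float = 0.01

    def __post_init__(self) -> None:
        if any(d <= 0 for d, _ in self.standards):
            raise ValueError("dilution factors must be positive")
        if len({d for d, _ in self.standards}) < 2:
            raise ValueError("need at least 2 distinct dilution levels")
        required = {"label", "replicate", "ct"}
        if not required <= set(self.samples.columns):
            raise ValueError(f"samples need columns {sorted(required)}")

    @classmethod
    def read_tsv(cls, standards_path, samples_path, start_mass=20.0,
                 input_fraction=0.01) -> "QpcrRun":
        std = pd.read_csv(standards_path, sep="\t")
        return cls(
            standards=list(zip(std["dilution"], std["ct"])),
            samples=pd.read_csv(samples_path, sep="\t"),
            start_mass=start_mass,
            input_fraction=input_fraction,
        )


def standard_curve(
    standards: Sequence[tuple[float, float]], start_mass: float = 20.0
) -> StandardCurve:
    """Least-squares Ct vs log10(mass); efficiency = 10^(-1/slope) - 1."""
    masses = [start_mass / d for d, _ in standards]
    cts = [ct for _, ct in standards]
    if len(set(masses)) < 2:
        raise ValueError("degenerate standards: need >= 2 distinct masses")
    x = np.log10(masses)
    res = stats.linregress(x, cts)
    eff = 10 ** (-1.0 / res.slope) - 1.0
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        efficiency=float(eff),
        r_squared=float(res.rvalue**2),
    )


@dataclass(frozen=True)
class ChipResult:
    percent_input: dict[str, float]  # label -> mean percent input
    percent_input_sd: dict[str, float]
    fold_change: float  # antibody vs IgG
    p_value: float  # two-tailed t test across replicate percent inputs
    curve: StandardCurve


def chip_enrichment(
    run: QpcrRun,
    antibody_label: str = "bra",
    igg_label: str = "igg",
    input_label: str = "input",
) -> ChipResult:
    """Percent input per sample, antibody/IgG fold change and a t-test p.

    percent input = 100 * quantity_IP / (quantity_input / input_fraction),
    computed per replicate (each IP paired with its replicate's input).
    """
    labels = set(run.samples["label"])
    for lab in (antibody_label, igg_label, input_label):
        if lab not in labels:
            raise ValueError(f"run is missing required sample label {lab!r}")
    curve = standard_curve(run.standards, run.start_mass)
    q = run.samples.copy()
    q["quantity"] = q["ct"].map(curve.quantity)

    def per_replicate(lab: str) -> pd.Series:
        ip = q[q["label"] == lab].set_index("replicate")["quantity"]
        inp = q[q["label"] == input_label].set_index("replicate")["quantity"]
        common = ip.index.intersection(inp.index)
        if common.empty:
            raise ValueError(f"no replicate pairing between {lab!r} and input")
        return 100.0 * ip.loc[common] / (inp.loc[common] / run.input_fraction)

    pct_bra = per_replicate(antibody_label)
    pct_igg = per_replicate(igg_label)
    fold = float(pct_bra.mean() / pct_igg.mean())
    if len(pct_bra) >= 2 and len(pct_igg) >= 2:
        p = float(stats.ttest_ind(pct_bra, pct_igg).pvalue)
        if math.isnan(p):  # identical constant samples
            p = 1.0
    else:
        p = float("nan")
    return ChipResult(
        percent_input={
            antibody_label: float(pct_bra.mean()),
            igg_label: float(pct_igg.mean()),
        },
        percent_input_sd={
            antibody_label: float(pct_bra.std(ddof=1)) if len(pct_bra) > 1 else 0.0,
            igg_label: float(pct_igg.std(ddof=1)) if len(pct_igg) > 1 else 0.0,
        },
        fold_change=fold,
        p_value=p,
        curve=curve,
    )
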