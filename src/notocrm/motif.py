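"""Degenerate IUPAC pattern algebra, binding-site catalogs and consensus arithmetic.

The model is deliberately consensus/mismatch-based: a 6-bp degenerate core
(``TNNCAC``) identifies candidate T-box binding sites, and a 12-bp extended
frame (``RWWNTNRCACYT``, core at positions 5-10) scores flank fidelity by
counting positions that fail the degenerate consensus.  No PWM or affinity
scoring is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "IUPAC_SETS",
    "CORE_PATTERN",
    "EXTENDED_CONSENSUS",
    "CORE_OFFSET_IN_FRAME",
    "IupacPattern",
    "CoreEntry",
    "FunctionalSite",
    "MismatchReport",
    "SiteCatalog",
    "InvalidAlphabetError",
    "iupac_matches",
    "pattern_match",
    "revcomp",
    "consensus_mismatches",
    "core_status",
    "build_consensus",
    "load_catalog",
]

#: IUPAC nucleotide codes mapped to the set of concrete bases they admit.
IUPAC_SETS: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

# reverse lookup: base set -> minimal covering IUPAC code
_SET_TO_CODE: Mapping[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

_COMPLEMENT = str.maketrans("ACGTNRYWSKMBDHVacgtnrywskmbdhv",
                            "TGCANYRWSMKVHDBtgcanyrwsmkvhdb")

# 0-based offset of the 6-bp core within the 12-bp extended frame:
# 4 bases of 5' flank, then the core, then 2 bases of 3' flank.
CORE_OFFSET_IN_FRAME = 4


class InvalidAlphabetError(ValueError):
    """A base or IUPAC code outside the supported alphabet."""


@dataclass(frozen=True)
class IupacPattern:
    """A fixed-length degenerate nucleotide pattern."""

    symbols: str

    def __post_init__(self) -> None:
        s = self.symbols.upper()
        if len(s) < 1:
            raise ValueError("pattern must have length >= 1")
        for c in s:
            if c not in IUPAC_SETS:
                raise InvalidAlphabetError(f"invalid IUPAC code {c!r}")
        object.__setattr__(self, "symbols", s)

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return self.symbols

    def __iter__(self):
        return iter(self.symbols)

    def reverse_complement(self) -> "IupacPattern":
        return IupacPattern(self.symbols.translate(_COMPLEMENT)[::-1])


CORE_PATTERN = IupacPattern("TNNCAC")
EXTENDED_CONSENSUS = IupacPattern("RWWNTNRCACYT")


def iupac_matches(base: str, code: str) -> bool:
    """True iff ``base`` belongs to the degenerate set of ``code``.

    Comparison is case-insensitive.  An input base ``N`` (masked/ambiguous
    sequence) matches *no* code, including ``N`` — conservative policy so
    masked stretches never generate hits.
    """
    b, c = base.upper(), code.upper()
    if b not in ("A", "C", "G", "T", "N"):
        raise InvalidAlphabetError(f"invalid base {b!r}")
    if c not in IUPAC_SETS:
        raise InvalidAlphabetError(f"invalid IUPAC code {c!r}")
    if b == "N":
        return False
    return b in IUPAC_SETS[c]


def pattern_match(seq: str, pattern: IupacPattern) -> bool:
    """True iff ``seq`` matches ``pattern`` position by position."""
    if len(seq) != len(pattern):
        raise ValueError(
            f"sequence length {len(seq)} != pattern length {len(pattern)}"
        )
    return all(iupac_matches(b, c) for b, c in zip(seq, pattern.symbols))


def revcomp(seq: str) -> str:
    """Reverse complement over A/C/G/T/N (case preserved)."""
    for ch in seq.upper():
        if ch not in ("A", "C", "G", "T", "N"):
            raise InvalidAlphabetError(f"invalid base {ch!r}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MismatchReport:
    """Positions of a 12-bp site that fail the extended consensus (1-based)."""

    site12: str
    positions: frozenset[int]

    @property
    def count(self) -> int:
        return len(self.positions)


def consensus_mismatches(
    site12: str, consensus: IupacPattern = EXTENDED_CONSENSUS
) -> MismatchReport:
    """Report 1-based alignment positions of ``site12`` failing ``consensus``."""
    if len(site12) != len(consensus):
        raise ValueError(
            f"site length {len(site12)} != consensus length {len(consensus)}"
        )
    bad = frozenset(
        i + 1
        for i, (b, c) in enumerate(zip(site12, consensus.symbols))
        if not iupac_matches(b, c)
    )
    return MismatchReport(site12=site12, positions=bad)


@dataclass(frozen=True)
class CoreEntry:
    hexamer: str
    status: str  # required | represented_only | unobserved
    evidence: str  # ChIP | EMSA | none
    contexts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.status not in ("required", "represented_only", "unobserved"):
            raise ValueError(f"bad status {self.status!r}")
        if not pattern_match(self.hexamer, CORE_PATTERN):
            raise ValueError(f"{self.hexamer!r} does not match the core pattern")


@dataclass(frozen=True)
class FunctionalSite:
    """A catalogued 12-bp functional site with printed case preserved."""

    name: str
    sequence12: str
    mechanism: str  # individual | cooperative

    def __post_init__(self) -> None:
        if len(self.sequence12) != 12:
            raise ValueError("functional site must be 12 bp")
        if self.mechanism not in ("individual", "cooperative"):
            raise ValueError(f"bad mechanism {self.mechanism!r}")

    @property
    def core(self) -> str:
        """The 6-bp core at alignment positions 5-10, uppercased."""
        return self.sequence12.upper()[
            CORE_OFFSET_IN_FRAME : CORE_OFFSET_IN_FRAME + 6
        ]

    @property
    def lowercase_positions(self) -> frozenset[int]:
        """1-based positions printed lowercase (divergence marks)."""
        return frozenset(
            i + 1 for i, ch in enumerate(self.sequence12) if ch.islower()
        )


@dataclass(frozen=True)
class SiteCatalog:
    """Packaged knowledge of core occurrence/requirement and functional sites."""

    cores: Mapping[str, CoreEntry]
    sites: tuple[FunctionalSite, ...]

    def status_of(self, hexamer: str) -> str:
        return core_status(hexamer, self)

    def whitelist(self, mode: str = "required_only") -> frozenset[str]:
        """Core hexamers accepted as confident under a whitelist mode."""
        if mode == "required_only":
            keep = ("required",)
        elif mode == "required_plus_represented":
            keep = ("required", "represented_only")
        else:
            raise ValueError(f"unknown whitelist mode {mode!r}")
        return frozenset(h for h, e in self.cores.items() if e.status in keep)

    def sites_for_core(self, hexamer: str) -> tuple[FunctionalSite, ...]:
        hx = hexamer.upper()
        return tuple(s for s in self.sites if s.core == hx)


def core_status(hexamer: str, catalog: SiteCatalog) -> str:
    """Catalog status of a core hexamer (required/represented_only/unobserved)."""
    hx = hexamer.upper()
    if not pattern_match(hx, CORE_PATTERN):
        raise ValueError(f"{hexamer!r} does not match the core pattern TNNCAC")
    return catalog.cores[hx].status


def _read_packaged(name: str) -> list[list[str]]:
    text = (resources.files("notocrm.data") / name).read_text(encoding="utf-8")
    rows = [line.split("\t") for line in text.splitlines() if line.strip()]
    return rows[1:]  # drop header


def load_catalog() -> SiteCatalog:
    """Load the packaged core and functional-site catalogs."""
    cores: dict[str, CoreEntry] = {}
    for row in _read_packaged("core_catalog.tsv"):
        hexamer, status, evidence = row[0], row[1], row[2]
        ctx = tuple(c for c in (row[3].split(";") if len(row) > 3 else []) if c)
        cores[hexamer] = CoreEntry(hexamer, status, evidence, ctx)
    if len(cores) != 16:
        raise RuntimeError(f"core catalog must have 16 rows, got {len(cores)}")
    sites = tuple(
        FunctionalSite(name=r[0], sequence12=r[1], mechanism=r[2])
        for r in _read_packaged("functional_sites.tsv")
    )
    if len(sites) != 24:
        raise RuntimeError(f"site catalog must have 24 rows, got {len(sites)}")
    return SiteCatalog(cores=cores, sites=sites)


@dataclass(frozen=True)
class ConsensusBuild:
    pattern: IupacPattern
    frequencies: tuple[Mapping[str, float], ...]  # per position, A/C/G/T -> freq


def build_consensus(
    sites: Sequence[str], degeneracy_threshold: float = 0.05
) -> ConsensusBuild:
    """Derive a minimal-cover degenerate consensus from aligned sites.

    At each position, bases whose observed frequency is at least
    ``degeneracy_threshold`` are covered by the smallest IUPAC code whose
    base set contains them all.
    """
    if len(sites) < 2:
        raise ValueError("need at least 2 sites to build a consensus")
    width = len(sites[0])
    ups = [s.upper() for s in sites]
    for s in ups:
        if len(s) != width:
            raise ValueError("all sites must share one length")
    freqs: list[dict[str, float]] = []
    symbols: list[str] = []
    n = len(ups)
    for j in range(width):
        counts = {b: 0 for b in "ACGT"}
        for s in ups:
            if s[j] not in counts:
                raise InvalidAlphabetError(f"invalid base {s[j]!r} at column {j}")
            counts[s[j]] += 1
        f = {b: counts[b] / n for b in "ACGT"}
        freqs.append(f)
        kept = frozenset(b for b in "ACGT" if f[b] >= degeneracy_threshold)
        if not kept:  # threshold above every frequency: keep the modal base(s)
            top = max(f.values())
            kept = frozenset(b for b in "ACGT" if f[b] == top)
        symbols.append(_minimal_cover(kept))
    return ConsensusBuild(
        pattern=IupacPattern("".join(symbols)), frequencies=tuple(freqs)
    )


def _minimal_cover(bases: frozenset[str]) -> str:
    if bases in _SET_TO_CODE:
        return _SET_TO_CODE[bases]
    # smallest superset code
    best = min(
        (code for code, s in IUPAC_SETS.items() if bases <= s),
        key=lambda code: len(IUPAC_SETS[code]),
    )
    return best
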