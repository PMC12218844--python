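"""Shared domain types for the trio DNM pipeline.

Coordinates follow the conventions of the formats they mirror: VCF-style
site positions are 1-based inclusive, interval types (islands, windows,
masks) are 0-based half-open. Every container here is a plain dataclass so
that modules can exchange records without import cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

Genotype = Optional[tuple[int, int]]  # None encodes a missing call ("./.")


@dataclass
class SampleCall:
    """Per-sample evidence at one site: genotype, depth, allele depths, GQ."""

    gt: Genotype
    dp: int = 0
    ad: Optional[tuple[int, int]] = None  # (ref reads, alt reads)
    gq: Optional[int] = None

    @property
    def is_het(self) -> bool:
        return self.gt is not None and sorted(self.gt) == [0, 1]

    @property
    def is_hom_ref(self) -> bool:
        return self.gt == (0, 0)

    @property
    def is_hom_alt(self) -> bool:
        return self.gt == (1, 1)

    @property
    def allelic_balance(self) -> Optional[float]:
        """Alternate-read fraction alt/(ref+alt); None without reads."""
        if self.ad is None:
            return None
        tot = self.ad[0] + self.ad[1]
        if tot == 0:
            return None
        return self.ad[1] / tot


@dataclass
class SiteRecord:
    """One biallelic site (or a monomorphic depth-survey record, alt=None)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: Optional[str]
    info: dict[str, float] = field(default_factory=dict)
    calls: dict[str, SampleCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.alt is not None and self.ref == self.alt:
            raise ValueError("ref and alt must differ")


@dataclass(frozen=True)
class Trio:
    """A father-mother-child unit; the atom of Mendelian-violation calling."""

    family: str
    father: str
    mother: str
    child: str

    def __post_init__(self) -> None:
        if len({self.father, self.mother, self.child}) != 3:
            raise ValueError("trio members must be three distinct samples")

    @property
    def members(self) -> tuple[str, str, str]:
        return (self.father, self.mother, self.child)


@dataclass
class DnmCandidate:
    """A Mendelian-violation call and everything the funnel learned about it."""

    trio: Trio
    chrom: str
    pos: int
    ref: str
    alt: str
    filter_trail: list[tuple[str, bool]] = field(default_factory=list)
    validation: Optional[str] = None  # validated | rejected_* | unvalidatable
    shared_group: Optional[str] = None
    origin: str = "unknown"  # paternal | maternal | unknown
    context: Optional[str] = None  # filled by the spectrum module

    @property
    def passed_filters(self) -> bool:
        return all(ok for _, ok in self.filter_trail)

    @property
    def key(self) -> tuple[str, str, int, str]:
        """Identity used for full-sib sharing: (family, chrom, pos, alt)."""
        return (self.trio.family, self.chrom, self.pos, self.alt)


@dataclass
class CallableSummary:
    """Callable genome size for one offspring."""

    offspring: str
    cs: float  # bp
    autosome_total: float  # bp

    @property
    def callable_fraction(self) -> float:
        return self.cs / self.autosome_total if self.autosome_total else 0.0


@dataclass
class ReadEvidence:
    """One sequencing fragment: allele observations at one or more sites."""

    fragment_id: str
    sample: str
    observations: list[tuple[str, int, str]]  # (chrom, pos, base)


@dataclass
class PlantedDnm:
    """Ground-truth record of one simulated germline mutation event."""

    family: str
    offspring: tuple[str, ...]
    chrom: str
    pos: int
    ref: str
    alt: str
    parent_of_origin: str  # paternal | maternal
    pre_pgc: bool
    cpg: bool


@dataclass
class TruthSet:
    """Simulator ground truth used by the recovery test-benches."""

    planted_dnms: list[PlantedDnm]
    per_offspring_true_count: dict[str, int]
    false_positive_sites: list[tuple[str, str, int, str, str]] = field(
        default_factory=list
    )  # (child, chrom, pos, ref, alt)
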