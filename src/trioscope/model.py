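"""Core domain types shared by every other module.

All coordinates are 0-based half-open internally; the VCF convention
(1-based ``pos``) appears only on :class:`VariantKey`, which mirrors the
on-disk record it keys. No I/O happens here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "GenomicRegion",
    "VariantKey",
    "NormalizedVariant",
    "GenotypeCall",
    "AlleleCounts",
    "Individual",
    "Pedigree",
    "PopulationRecord",
    "ClinVarSignificance",
    "ClinVarAssertion",
    "Impact",
    "AnnotationBundle",
    "InheritanceMode",
    "InheritanceCall",
    "Verdict",
    "AdjudicationResult",
    "CoverageSummary",
    "ReviewSignificance",
    "ReviewRecord",
    "DEFAULT_REGION_PADDING",
    "is_x_contig",
    "is_y_contig",
]

DEFAULT_REGION_PADDING = 1000

ALLELE_ALPHABET = frozenset("ACGTN")

#: Contig aliases for the sex chromosomes. PAR handling is deliberately
#: conservative: without an explicit PAR BED the whole X is treated as
#: hemizygous in males.
X_ALIASES = frozenset({"X", "chrX"})
Y_ALIASES = frozenset({"Y", "chrY"})


def is_x_contig(contig: str, aliases: frozenset[str] = X_ALIASES) -> bool:
    return contig in aliases


def is_y_contig(contig: str, aliases: frozenset[str] = Y_ALIASES) -> bool:
    return contig in aliases


class InvalidRegionError(ValueError):
    """Raised when a genomic interval is empty or inverted."""


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """Half-open interval [start, end) on a contig, 0-based."""

    contig: str
    start: int
    end: int
    padding: int = 0

    def __post_init__(self) -> None:
        if self.padding < 0:
            raise InvalidRegionError(f"padding must be >= 0, got {self.padding}")
        if not (0 <= self.start < self.end):
            raise InvalidRegionError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # samtools-style, 1-based inclusive
        return f"{self.contig}:{self.start + 1}-{self.end}"


def make_region(
    contig: str,
    gene_start: int,
    gene_end: int,
    padding: int = DEFAULT_REGION_PADDING,
) -> GenomicRegion:
    """Analysis region for a gene: its coordinates widened by ``padding``
    bp on each side, clamped at the contig origin.
    """
    if gene_start >= gene_end:
        raise InvalidRegionError(
            f"gene interval empty or inverted: [{gene_start}, {gene_end})"
        )
    if padding < 0:
        raise InvalidRegionError(f"padding must be >= 0, got {padding}")
    return GenomicRegion(
        contig=contig,
        start=max(0, gene_start - padding),
        end=gene_end + padding,
        padding=padding,
    )


@dataclass(frozen=True, order=True)
class VariantKey:
    """A biallelic contig/pos/ref/alt allele; ``pos`` is 1-based (VCF).

    This is the join key for all annotation, so construction enforces the
    post-decomposition contract: exactly one alt, non-empty alleles over
    {A,C,G,T,N}, ref != alt.
    """

    contig: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos is 1-based, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= ALLELE_ALPHABET:
                raise ValueError(f"{name} allele {allele!r} not over {{A,C,G,T,N}}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r})")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def __str__(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}>{self.alt}"


def _is_parsimonious(ref: str, alt: str) -> bool:
    if len(ref) == 1 and len(alt) == 1:
        return True
    if ref[-1] == alt[-1]:
        return False
    if len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        return False
    return True


@dataclass(frozen=True)
class NormalizedVariant:
    """A variant in canonical (decomposed, left-aligned, trimmed) form,
    with a provenance link to its pre-normalization spelling."""

    key: VariantKey
    original: VariantKey

    def __post_init__(self) -> None:
        if not _is_parsimonious(self.key.ref, self.key.alt):
            raise ValueError(f"{self.key} is not parsimonious")


@dataclass(frozen=True)
class GenotypeCall:
    """A called genotype for one sample. ``alleles`` holds allele indices
    (0 = ref); ``None`` entries are missing ('.'). Hemizygous calls carry a
    single allele. ``n_alleles`` is the record's total allele count — 2 for
    the biallelic records all downstream analysis runs on; raw
    multi-allelic records (pre-decomposition) may carry more.
    ``allele_depths`` holds per-allele read depths in allele order."""

    sample_id: str
    alleles: tuple[Optional[int], ...]
    phased: bool = False
    allele_depths: Optional[tuple[int, ...]] = None
    depth: Optional[int] = None
    quality: Optional[float] = None
    n_alleles: int = 2

    def __post_init__(self) -> None:
        if not 1 <= len(self.alleles) <= 2:
            raise ValueError("genotype must carry one or two alleles")
        for a in self.alleles:
            if a is not None and not 0 <= a < self.n_alleles:
                raise ValueError(
                    f"allele index {a} invalid for a record with "
                    f"{self.n_alleles} alleles"
                )
        if self.allele_depths is not None and self.depth is not None:
            if sum(self.allele_depths) > self.depth:
                raise ValueError("allele depths exceed total depth")

    @property
    def is_called(self) -> bool:
        return all(a is not None for a in self.alleles)

    @property
    def alt_count(self) -> Optional[int]:
        if not self.is_called:
            return None
        return sum(self.alleles)  # type: ignore[arg-type]

    @property
    def is_hom_ref(self) -> bool:
        return self.is_called and self.alt_count == 0

    @property
    def is_het(self) -> bool:
        return len(self.alleles) == 2 and self.is_called and self.alt_count == 1

    @property
    def is_hom_alt(self) -> bool:
        return self.is_called and self.alt_count == len(self.alleles)

    @property
    def is_hemizygous(self) -> bool:
        return len(self.alleles) == 1

    def gt_string(self) -> str:
        sep = "|" if self.phased else "/"
        return sep.join("." if a is None else str(a) for a in self.alleles)


@dataclass(frozen=True)
class AlleleCounts:
    """Read observations at one site for one sample."""

    ref_obs: int
    alt_obs: int
    other_obs: int = 0

    def __post_init__(self) -> None:
        if min(self.ref_obs, self.alt_obs, self.other_obs) < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.ref_obs + self.alt_obs + self.other_obs

    @property
    def alt_fraction(self) -> Optional[float]:
        if self.depth == 0:
            return None
        return self.alt_obs / self.depth


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affected(enum.Enum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Individual:
    id: str
    sex: Sex = Sex.UNKNOWN
    affected: Affected = Affected.UNKNOWN
    mother_id: Optional[str] = None
    father_id: Optional[str] = None


@dataclass(frozen=True)
class Pedigree:
    """Family structure driving inheritance and violation logic."""

    members: tuple[Individual, ...]
    proband_id: str

    def __post_init__(self) -> None:
        ids = {m.id for m in self.members}
        if len(ids) != len(self.members):
            raise ValueError("duplicate sample ids in pedigree")
        if self.proband_id not in ids:
            raise ValueError(f"proband {self.proband_id!r} not among members")
        for m in self.members:
            for ref in (m.mother_id, m.father_id):
                if ref is not None and ref not in ids:
                    raise ValueError(f"{m.id}: parent {ref!r} not in pedigree")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        by_id = {m.id: m for m in self.members}
        for start in by_id:
            seen: set[str] = set()
            stack = [start]
            while stack:
                cur = stack.pop()
                for parent in (by_id[cur].mother_id, by_id[cur].father_id):
                    if parent is None:
                        continue
                    if parent == start:
                        raise ValueError(f"{start} is its own ancestor")
                    if parent not in seen:
                        seen.add(parent)
                        stack.append(parent)

    def __getitem__(self, sample_id: str) -> Individual:
        for m in self.members:
            if m.id == sample_id:
                return m
        raise KeyError(sample_id)

    def __contains__(self, sample_id: str) -> bool:
        return any(m.id == sample_id for m in self.members)

    @property
    def proband(self) -> Individual:
        return self[self.proband_id]

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.members)

    def siblings_of(self, sample_id: str) -> tuple[Individual, ...]:
        me = self[sample_id]
        if me.mother_id is None and me.father_id is None:
            return ()
        return tuple(
            m
            for m in self.members
            if m.id != sample_id
            and (m.mother_id, m.father_id) == (me.mother_id, me.father_id)
        )


@dataclass(frozen=True)
class PopulationRecord:
    """Population-aggregate annotation: allele frequency plus carrier
    counts (heterozygous and homozygous-alternate individuals)."""

    allele_frequency: Optional[float]
    het_count: Optional[int] = None
    hom_alt_count: Optional[int] = None
    missing_fields: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        af = self.allele_frequency
        if af is not None and not 0.0 <= af <= 1.0:
            raise ValueError(f"allele frequency {af} outside [0, 1]")
        for name, count in (
            ("het_count", self.het_count),
            ("hom_alt_count", self.hom_alt_count),
        ):
            if count is not None and count < 0:
                raise ValueError(f"{name} must be >= 0")


class ClinVarSignificance(enum.IntEnum):
    """Clinical-significance tiers, most severe first (lower sorts first)."""

    PATHOGENIC = 0
    LIKELY_PATHOGENIC = 1
    CONFLICTING = 2
    UNCERTAIN = 3
    LIKELY_BENIGN = 4
    BENIGN = 5
    NONE = 6


@dataclass(frozen=True)
class ClinVarAssertion:
    significance: ClinVarSignificance
    review_status: str = ""


class Impact(enum.IntEnum):
    """Coarse severity tier of a functional consequence (most severe first)."""

    HIGH = 0
    MODERATE = 1
    LOW = 2
    MODIFIER = 3


@dataclass(frozen=True)
class AnnotationBundle:
    """Everything attached to a variant by annotation: functional
    consequence + impact, in-silico score, HGVS, identifiers, clinical
    assertion and population record."""

    consequence: str = ""
    impact: Optional[Impact] = None
    revel: Optional[float] = None
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    dbsnp_id: Optional[str] = None
    clinvar: Optional[ClinVarAssertion] = None
    population: Optional[PopulationRecord] = None
    transcript_id: Optional[str] = None
    gene: Optional[str] = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.revel is not None and not 0.0 <= self.revel <= 1.0:
            raise ValueError(f"REVEL score {self.revel} outside [0, 1]")


class InheritanceMode(enum.IntEnum):
    """Mendelian mode of inheritance, ranked by prioritization interest."""

    DENOVO = 0
    AUTOSOMAL_RECESSIVE = 1
    X_LINKED_RECESSIVE = 2
    AUTOSOMAL_DOMINANT = 3
    UNKNOWN = 4
    NONE = 5


@dataclass(frozen=True)
class InheritanceCall:
    mode: InheritanceMode
    violation: bool = False
    reason: str = ""

    def __post_init__(self) -> None:
        if self.violation and self.mode == InheritanceMode.DENOVO:
            raise ValueError("a de novo call cannot itself be a Mendelian violation")


class Verdict(enum.Enum):
    SUPPORTED = "supported"
    LIKELY_FALSE_POSITIVE = "likely_false_positive"
    POSSIBLY_INHERITED = "possibly_inherited"
    INSUFFICIENT_DATA = "insufficient_data"


@dataclass(frozen=True)
class AdjudicationResult:
    verdict: Verdict
    proband_ab: Optional[float]
    parent_ab: dict[str, Optional[float]] = field(default_factory=dict)
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class CoverageSummary:
    region: GenomicRegion
    min: int
    max: int
    median: float
    mean: float

    def __post_init__(self) -> None:
        if not (self.min <= self.median <= self.max):
            raise ValueError("median outside [min, max]")
        if not (self.min <= self.mean <= self.max):
            raise ValueError("mean outside [min, max]")


class ReviewSignificance(enum.IntEnum):
    """User-assigned review tiers (research vocabulary, deliberately not
    ACMG/AMP terms), in prioritization order."""

    SIGNIFICANT = 0
    UNKNOWN_SIGNIFICANCE = 1
    NOT_REVIEWED = 2
    NOT_SIGNIFICANT = 3
    POOR_QUALITY = 4

    @classmethod
    def from_label(cls, label: str) -> "ReviewSignificance":
        try:
            return _REVIEW_LABELS[label]
        except KeyError:
            allowed = ", ".join(sorted(_REVIEW_LABELS))
            raise ValueError(
                f"unknown significance {label!r}; allowed: {allowed}"
            ) from None

    @property
    def label(self) -> str:
        return {
            ReviewSignificance.SIGNIFICANT: "Significant",
            ReviewSignificance.UNKNOWN_SIGNIFICANCE: "Unknown significance",
            ReviewSignificance.NOT_SIGNIFICANT: "Not significant",
            ReviewSignificance.POOR_QUALITY: "Poor quality",
            ReviewSignificance.NOT_REVIEWED: "Not reviewed",
        }[self]


_REVIEW_LABELS = {sig.label: sig for sig in ReviewSignificance}


@dataclass(frozen=True)
class ReviewRecord:
    variant: VariantKey
    significance: ReviewSignificance
    note: str = ""
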