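"""Deterministic prioritization, filtering, review assignment and
lossless export/import of analyses.

The prioritization order is a six-level lexicographic tuple: review
status first (Significant < Unknown significance < Not reviewed < Not
significant < Poor quality), then clinical assertion (pathogenic <
likely_pathogenic < conflicting < uncertain < no assertion <
likely_benign < benign), mode of inheritance (de novo first), impact
(HIGH first), population allele frequency ascending with "never observed
in the population set" ranking rarest of all, and finally genomic
coordinates as the tie-break. Missing components rank last within their
tier, so the order is total over arbitrary records.

Exports are either a VCF with declared String INFO tags (free text
percent-encoded) or an RFC-4180 CSV with a mandatory header; importing an
export reproduces every variant key, annotation value, significance and
note exactly.
"""

from __future__ import annotations

import csv
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pysam

from .model import (
    AnnotationBundle,
    ClinVarAssertion,
    ClinVarSignificance,
    Impact,
    InheritanceCall,
    InheritanceMode,
    PopulationRecord,
    ReviewRecord,
    ReviewSignificance,
    VariantKey,
    Verdict,
)

__all__ = [
    "AnalysisRecord",
    "ReviewStore",
    "sort_key",
    "rank",
    "filter_records",
    "export_analysis",
    "import_analysis",
]


@dataclass(frozen=True)
class AnalysisRecord:
    """One fully annotated variant as it appears in the ranked list."""

    key: VariantKey
    bundle: AnnotationBundle = field(default_factory=AnnotationBundle)
    inheritance: Optional[InheritanceCall] = None
    verdict: Optional[Verdict] = None
    filters: tuple[str, ...] = ()


#: Ranking positions for clinical assertions; "no assertion" sits between
#: uncertain and likely_benign.
_CLINVAR_RANK = {
    ClinVarSignificance.PATHOGENIC: 0,
    ClinVarSignificance.LIKELY_PATHOGENIC: 1,
    ClinVarSignificance.CONFLICTING: 2,
    ClinVarSignificance.UNCERTAIN: 3,
    ClinVarSignificance.NONE: 4,
    ClinVarSignificance.LIKELY_BENIGN: 5,
    ClinVarSignificance.BENIGN: 6,
}


def sort_key(
    record: AnalysisRecord, review: Optional[ReviewRecord] = None
) -> tuple:
    """Lexicographic prioritization tuple; smaller sorts first."""
    sig = review.significance if review else ReviewSignificance.NOT_REVIEWED
    clinvar = record.bundle.clinvar
    clin = _CLINVAR_RANK[clinvar.significance] if clinvar else _CLINVAR_RANK[
        ClinVarSignificance.NONE
    ]
    mode = int(record.inheritance.mode) if record.inheritance else len(InheritanceMode)
    impact = int(record.bundle.impact) if record.bundle.impact is not None else len(Impact)
    pop = record.bundle.population
    af = (
        pop.allele_frequency
        if pop is not None and pop.allele_frequency is not None
        else -1.0  # never observed: rarer than any numeric frequency
    )
    k = record.key
    return (int(sig), clin, mode, impact, af, k.contig, k.pos, k.ref, k.alt)


class ReviewStore:
    """Reviews keyed by normalized variant key; overwrites retain history."""

    def __init__(self) -> None:
        self._history: dict[VariantKey, list[ReviewRecord]] = {}

    def set_review(
        self,
        variant: VariantKey,
        significance: ReviewSignificance | str,
        note: str = "",
    ) -> ReviewRecord:
        if isinstance(significance, str):
            significance = ReviewSignificance.from_label(significance)
        record = ReviewRecord(variant=variant, significance=significance, note=note)
        self._history.setdefault(variant, []).append(record)
        return record

    def get_review(self, variant: VariantKey) -> Optional[ReviewRecord]:
        hist = self._history.get(variant)
        return hist[-1] if hist else None

    def history(self, variant: VariantKey) -> tuple[ReviewRecord, ...]:
        return tuple(self._history.get(variant, ()))

    def __len__(self) -> int:
        return len(self._history)

    def __iter__(self) -> Iterable[VariantKey]:
        return iter(self._history)


def rank(
    records: Sequence[AnalysisRecord], reviews: Optional[ReviewStore] = None
) -> list[AnalysisRecord]:
    reviews = reviews or ReviewStore()
    return sorted(records, key=lambda r: sort_key(r, reviews.get_review(r.key)))


def filter_records(
    records: Sequence[AnalysisRecord],
    max_af: Optional[float] = None,
    min_impact: Optional[Impact | str] = None,
    modes: Optional[Sequence[InheritanceMode | str]] = None,
    clinvar_only: bool = False,
    pass_only: bool = False,
) -> tuple[list[AnalysisRecord], dict[str, int]]:
    """Subset satisfying the conjunction of criteria, plus how many
    records each criterion removed. A variant absent from the population
    set passes any ``max_af`` (it is rarer than any numeric frequency)."""
    if isinstance(min_impact, str):
        min_impact = Impact[min_impact]
    mode_set = None
    if modes is not None:
        mode_set = {
            InheritanceMode[m.upper()] if isinstance(m, str) else m for m in modes
        }
    removed = {"af": 0, "impact": 0, "mode": 0, "clinvar": 0, "filter": 0}
    kept = []
    for rec in records:
        pop = rec.bundle.population
        af = pop.allele_frequency if pop else None
        if max_af is not None and af is not None and af > max_af:
            removed["af"] += 1
            continue
        if min_impact is not None and (
            rec.bundle.impact is None or rec.bundle.impact > min_impact
        ):
            removed["impact"] += 1
            continue
        if mode_set is not None and (
            rec.inheritance is None or rec.inheritance.mode not in mode_set
        ):
            removed["mode"] += 1
            continue
        if clinvar_only and (
            rec.bundle.clinvar is None
            or rec.bundle.clinvar.significance == ClinVarSignificance.NONE
        ):
            removed["clinvar"] += 1
            continue
        if pass_only and rec.filters not in ((), ("PASS",)):
            removed["filter"] += 1
            continue
        kept.append(rec)
    return kept, removed


# ---------------------------------------------------------------------------
# export / import

_CSV_COLUMNS = [
    "contig", "pos", "ref", "alt",
    "consequence", "impact", "revel", "hgvs_c", "hgvs_p", "dbsnp_id",
    "clinvar_significance", "clinvar_review_status",
    "population_af", "population_het", "population_hom",
    "inheritance_mode", "mendelian_violation", "inheritance_reason",
    "denovo_verdict", "filters",
    "review_significance", "review_note",
]

#: INFO tags written on VCF export. All String-typed so values round-trip
#: byte-exactly; free text is percent-encoded.
_VCF_TAGS = {
    "CONSEQUENCE": "Functional consequence term",
    "IMPACT": "Consequence impact tier",
    "REVEL": "REVEL ensemble missense score",
    "HGVSC": "HGVS coding-sequence name (percent-encoded)",
    "HGVSP": "HGVS protein name (percent-encoded)",
    "DBSNP": "dbSNP identifier",
    "CLNSIG_JOIN": "Joined clinical significance",
    "CLNREVSTAT_JOIN": "Joined clinical review status (percent-encoded)",
    "GN_AF": "Joined population allele frequency",
    "GN_HET": "Joined population heterozygote count",
    "GN_HOM": "Joined population homozygous-alternate count",
    "MOI": "Mode of inheritance",
    "MENDEL_VIOL": "Mendelian violation flag (0/1)",
    "MOI_REASON": "Inheritance call reason (percent-encoded)",
    "DN_VERDICT": "De novo adjudication verdict",
    "REVIEW_SIG": "Review significance (percent-encoded)",
    "REVIEW_NOTE": "Review note (percent-encoded)",
}


def _enc(text: str) -> str:
    return urllib.parse.quote(text, safe="")


def _dec(text: str) -> str:
    return urllib.parse.unquote(text)


def _record_to_row(rec: AnalysisRecord, review: Optional[ReviewRecord]) -> dict:
    b = rec.bundle
    clin = b.clinvar
    pop = b.population
    inh = rec.inheritance
    return {
        "contig": rec.key.contig,
        "pos": rec.key.pos,
        "ref": rec.key.ref,
        "alt": rec.key.alt,
        "consequence": b.consequence,
        "impact": b.impact.name if b.impact is not None else "",
        "revel": repr(b.revel) if b.revel is not None else "",
        "hgvs_c": b.hgvs_c or "",
        "hgvs_p": b.hgvs_p or "",
        "dbsnp_id": b.dbsnp_id or "",
        "clinvar_significance": clin.significance.name if clin else "",
        "clinvar_review_status": clin.review_status if clin else "",
        "population_af": (
            repr(pop.allele_frequency)
            if pop and pop.allele_frequency is not None
            else ("." if pop else "")
        ),
        "population_het": (
            str(pop.het_count) if pop and pop.het_count is not None else ("." if pop else "")
        ),
        "population_hom": (
            str(pop.hom_alt_count)
            if pop and pop.hom_alt_count is not None
            else ("." if pop else "")
        ),
        "inheritance_mode": inh.mode.name if inh else "",
        "mendelian_violation": ("1" if inh.violation else "0") if inh else "",
        "inheritance_reason": inh.reason if inh else "",
        "denovo_verdict": rec.verdict.value if rec.verdict else "",
        "filters": ";".join(rec.filters),
        "review_significance": review.significance.label if review else "",
        "review_note": review.note if review else "",
    }


def _record_from_row(row: dict) -> tuple[AnalysisRecord, Optional[tuple[str, str]]]:
    key = VariantKey(row["contig"], int(row["pos"]), row["ref"], row["alt"])
    clinvar = None
    if row["clinvar_significance"]:
        clinvar = ClinVarAssertion(
            significance=ClinVarSignificance[row["clinvar_significance"]],
            review_status=row["clinvar_review_status"],
        )
    population = None
    if row["population_af"] or row["population_het"] or row["population_hom"]:
        def _opt(v, cast):
            return None if v in ("", ".") else cast(v)
        population = PopulationRecord(
            allele_frequency=_opt(row["population_af"], float),
            het_count=_opt(row["population_het"], int),
            hom_alt_count=_opt(row["population_hom"], int),
        )
    bundle = AnnotationBundle(
        consequence=row["consequence"],
        impact=Impact[row["impact"]] if row["impact"] else None,
        revel=float(row["revel"]) if row["revel"] else None,
        hgvs_c=row["hgvs_c"] or None,
        hgvs_p=row["hgvs_p"] or None,
        dbsnp_id=row["dbsnp_id"] or None,
        clinvar=clinvar,
        population=population,
    )
    inheritance = None
    if row["inheritance_mode"]:
        inheritance = InheritanceCall(
            mode=InheritanceMode[row["inheritance_mode"]],
            violation=row["mendelian_violation"] == "1",
            reason=row["inheritance_reason"],
        )
    verdict = Verdict(row["denovo_verdict"]) if row["denovo_verdict"] else None
    filters = tuple(f for f in row["filters"].split(";") if f)
    record = AnalysisRecord(
        key=key,
        bundle=bundle,
        inheritance=inheritance,
        verdict=verdict,
        filters=filters,
    )
    review = None
    if row["review_significance"]:
        review = (row["review_significance"], row["review_note"])
    return record, review


def _export_csv(rows: list[dict], path: Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS, quoting=csv.QUOTE_MINIMAL)
        writer.writeheader()
        writer.writerows(rows)


_ROW_TO_TAG = {
    "consequence": "CONSEQUENCE",
    "impact": "IMPACT",
    "revel": "REVEL",
    "hgvs_c": "HGVSC",
    "hgvs_p": "HGVSP",
    "dbsnp_id": "DBSNP",
    "clinvar_significance": "CLNSIG_JOIN",
    "clinvar_review_status": "CLNREVSTAT_JOIN",
    "population_af": "GN_AF",
    "population_het": "GN_HET",
    "population_hom": "GN_HOM",
    "inheritance_mode": "MOI",
    "mendelian_violation": "MENDEL_VIOL",
    "inheritance_reason": "MOI_REASON",
    "denovo_verdict": "DN_VERDICT",
    "review_significance": "REVIEW_SIG",
    "review_note": "REVIEW_NOTE",
}
_TAG_TO_ROW = {v: k for k, v in _ROW_TO_TAG.items()}
#: Tags holding free text; percent-encoded so any byte survives VCF syntax.
_ENCODED_TAGS = {
    "HGVSC", "HGVSP", "CLNREVSTAT_JOIN", "MOI_REASON", "REVIEW_SIG", "REVIEW_NOTE",
}


def _export_vcf(rows: list[dict], path: Path) -> None:
    header = pysam.VariantHeader()
    for contig in dict.fromkeys(row["contig"] for row in rows):
        header.contigs.add(contig)
    for tag, desc in _VCF_TAGS.items():
        header.info.add(tag, 1, "String", desc)
    for row in rows:
        for f in row["filters"].split(";"):
            if f and f != "PASS" and f not in header.filters:
                header.filters.add(f, None, None, "carried over on export")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in rows:
            rec = out.new_record(
                contig=row["contig"],
                start=int(row["pos"]) - 1,
                alleles=(row["ref"], row["alt"]),
            )
            if row["filters"]:
                for f in row["filters"].split(";"):
                    if f:
                        rec.filter.add(f)
            for column, tag in _ROW_TO_TAG.items():
                value = row[column]
                if value == "":
                    continue
                rec.info[tag] = _enc(value) if tag in _ENCODED_TAGS else value
            out.write(rec)


def export_analysis(
    records: Sequence[AnalysisRecord],
    reviews: Optional[ReviewStore],
    format: str,
    path: str | Path,
) -> None:
    """Write a full analysis (annotations + latest reviews) as VCF or CSV."""
    if format not in ("vcf", "csv"):
        raise ValueError(f"format must be 'vcf' or 'csv', got {format!r}")
    reviews = reviews or ReviewStore()
    rows = [_record_to_row(r, reviews.get_review(r.key)) for r in records]
    path = Path(path)
    if format == "csv":
        _export_csv(rows, path)
    else:
        _export_vcf(rows, path)


def _sniff_format(path: Path) -> str:
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith(".csv"):
        return "csv"
    if suffix.endswith((".vcf", ".vcf.gz")):
        return "vcf"
    with open(path, "rb") as fh:
        head = fh.read(64)
    if head.startswith(b"\x1f\x8b") or head.startswith(b"##fileformat=VCF"):
        return "vcf"
    return "csv"


def _import_csv(path: Path) -> tuple[list[AnalysisRecord], ReviewStore]:
    records: list[AnalysisRecord] = []
    reviews = ReviewStore()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _CSV_COLUMNS:
            raise ValueError(
                f"{path}, line 1: not a trioscope analysis CSV "
                f"(header {reader.fieldnames!r})"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                record, review = _record_from_row(row)
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
            records.append(record)
            if review is not None:
                reviews.set_review(record.key, review[0], review[1])
    return records, reviews


def _import_vcf(path: Path) -> tuple[list[AnalysisRecord], ReviewStore]:
    records: list[AnalysisRecord] = []
    reviews = ReviewStore()
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ValueError(f"{path}: not a readable VCF ({exc})") from exc
    with vf:
        for lineno, rec in enumerate(vf, start=1):
            row = {c: "" for c in _CSV_COLUMNS}
            row.update(
                contig=rec.contig,
                pos=str(rec.pos),
                ref=rec.ref,
                alt=(rec.alts or ("",))[0],
                filters=";".join(rec.filter.keys()),
            )
            for tag, column in _TAG_TO_ROW.items():
                if tag in rec.info:
                    value = rec.info[tag]
                    if isinstance(value, tuple):
                        value = value[0]
                    value = str(value)
                    row[column] = _dec(value) if tag in _ENCODED_TAGS else value
            try:
                record, review = _record_from_row(row)
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}, record {lineno}: {exc}") from exc
            records.append(record)
            if review is not None:
                reviews.set_review(record.key, review[0], review[1])
    return records, reviews


def import_analysis(path: str | Path) -> tuple[list[AnalysisRecord], ReviewStore]:
    """Read back an exported analysis; the format is detected from the
    extension, then from content."""
    path = Path(path)
    if _sniff_format(path) == "csv":
        return _import_csv(path)
    return _import_vcf(path)
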