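"""Annotation joins against snapshot VCFs.

Population (gnomAD-style) and clinical (ClinVar-style) snapshots are
user-supplied indexed VCFs; there is no network fetch. Matching is
allele-exact on the canonical (decomposed, left-aligned) key, and the
snapshot side is normalized by this package's own normalizer before the
comparison, so any equivalent spelling of the query joins identically.

"Absent from the snapshot" is kept distinct from "AF = 0": downstream
ranking treats a variant never observed in the population set as rarer
than any numeric frequency.
"""

from __future__ import annotations

import logging
from typing import Optional

from .config import JoinConfig
from .model import (
    ClinVarAssertion,
    ClinVarSignificance,
    GenomicRegion,
    NormalizedVariant,
    PopulationRecord,
    VariantKey,
)
from .normalize import ReferenceFetch, decompose, left_align_trim, record_key
from .region_io import PathLike, fetch_variants

logger = logging.getLogger(__name__)

__all__ = ["CLNSIG_MAP", "join_population", "join_clinvar"]

#: ClinVar CLNSIG vocabulary -> ordered significance tiers. Combined
#: assertions map to the stronger tier; non-pathogenicity categories map
#: to NONE (present in ClinVar but uninformative for ranking).
CLNSIG_MAP: dict[str, ClinVarSignificance] = {
    "Pathogenic": ClinVarSignificance.PATHOGENIC,
    "Pathogenic/Likely_pathogenic": ClinVarSignificance.PATHOGENIC,
    "Likely_pathogenic": ClinVarSignificance.LIKELY_PATHOGENIC,
    "Conflicting_interpretations_of_pathogenicity": ClinVarSignificance.CONFLICTING,
    "Conflicting_classifications_of_pathogenicity": ClinVarSignificance.CONFLICTING,
    "Uncertain_significance": ClinVarSignificance.UNCERTAIN,
    "Likely_benign": ClinVarSignificance.LIKELY_BENIGN,
    "Benign/Likely_benign": ClinVarSignificance.LIKELY_BENIGN,
    "Benign": ClinVarSignificance.BENIGN,
    "drug_response": ClinVarSignificance.NONE,
    "risk_factor": ClinVarSignificance.NONE,
    "association": ClinVarSignificance.NONE,
    "Affects": ClinVarSignificance.NONE,
    "protective": ClinVarSignificance.NONE,
    "other": ClinVarSignificance.NONE,
    "not_provided": ClinVarSignificance.NONE,
}

#: How far left a snapshot spelling may shift during normalization and
#: still match; bounds the fetch window around the query.
_MATCH_WINDOW = 100


def _as_key(variant: NormalizedVariant | VariantKey) -> VariantKey:
    return variant.key if isinstance(variant, NormalizedVariant) else variant


def _trim_only(key: VariantKey) -> VariantKey:
    """Parsimony trimming without reference access (no left extension);
    used when no reference fetcher is supplied."""
    pos, ref, alt = key.pos, key.ref, key.alt
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(key.contig, pos, ref, alt)


def _normalized_snapshot_hits(
    snapshot_vcf: PathLike,
    query: VariantKey,
    reference_fetch: Optional[ReferenceFetch],
) -> list[tuple[VariantKey, dict]]:
    """(normalized key, per-alt INFO) for every snapshot allele near the
    query position."""
    start = max(0, query.pos - 1 - _MATCH_WINDOW)
    end = query.pos + len(query.ref) + _MATCH_WINDOW
    region = GenomicRegion(query.contig, start, end)
    try:
        records = fetch_variants(snapshot_vcf, region, samples=[])
    except Exception:
        raise
    hits: list[tuple[VariantKey, dict]] = []
    for record in records:
        for rec in decompose(record):
            if "symbolic_unnormalized" in rec.flags:
                continue
            try:
                key = record_key(rec)
            except ValueError:
                continue
            if reference_fetch is not None:
                try:
                    key = left_align_trim(key, reference_fetch).key
                except ValueError as exc:
                    logger.warning("snapshot record skipped: %s", exc)
                    continue
            else:
                key = _trim_only(key)
            hits.append((key, rec.info))
    return hits


def _scalar(value) -> Optional[str]:
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        value = value[0] if value else None
    return None if value is None else str(value)


def join_population(
    variant: NormalizedVariant | VariantKey,
    population_vcf: PathLike,
    field_map: JoinConfig = JoinConfig(),
    reference_fetch: Optional[ReferenceFetch] = None,
) -> Optional[PopulationRecord]:
    """Allele frequency and het/hom-alt carrier counts for an exact
    allele match, or None when the variant is not in the population set.

    Configured INFO fields missing from a matched record yield a partial
    record whose ``missing_fields`` names them.
    """
    query = _as_key(variant)
    for key, info in _normalized_snapshot_hits(population_vcf, query, reference_fetch):
        if key != query:
            continue
        missing = []
        af = _scalar(info.get(field_map.af_field))
        if af is None:
            missing.append(field_map.af_field)
        het = _scalar(info.get(field_map.het_field))
        if het is None:
            missing.append(field_map.het_field)
        hom = _scalar(info.get(field_map.hom_field))
        if hom is None:
            missing.append(field_map.hom_field)
        # htslib stores Float INFO in single precision; round back to the
        # snapshot's printed precision
        return PopulationRecord(
            allele_frequency=round(float(af), 6) if af is not None else None,
            het_count=int(het) if het is not None else None,
            hom_alt_count=int(hom) if hom is not None else None,
            missing_fields=tuple(missing),
        )
    return None


def join_clinvar(
    variant: NormalizedVariant | VariantKey,
    clinvar_vcf: PathLike,
    field_map: JoinConfig = JoinConfig(),
    reference_fetch: Optional[ReferenceFetch] = None,
) -> Optional[ClinVarAssertion]:
    """Clinical assertion for an exact allele match, or None. Significance
    strings outside the known vocabulary map to the NONE tier."""
    query = _as_key(variant)
    for key, info in _normalized_snapshot_hits(clinvar_vcf, query, reference_fetch):
        if key != query:
            continue
        raw = _scalar(info.get(field_map.clnsig_field))
        if raw is None:
            return ClinVarAssertion(
                significance=ClinVarSignificance.NONE, review_status=""
            )
        primary = raw.split(",")[0].split("|")[0].strip()
        significance = CLNSIG_MAP.get(primary)
        if significance is None:
            logger.warning("unrecognized clinical significance %r", primary)
            significance = ClinVarSignificance.NONE
        status = _scalar(info.get(field_map.review_status_field)) or ""
        return ClinVarAssertion(
            significance=significance, review_status=status.replace("_", " ")
        )
    return None
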