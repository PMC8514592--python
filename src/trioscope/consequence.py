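"""Functional consequence and impact annotation.

Two routes: parse pre-computed per-transcript CSQ annotations out of an
annotated VCF, or classify a normalized variant directly against a
transcript model with a minimal built-in classifier (SNV/MNV protein
comparison, indel frame arithmetic, canonical 2-bp splice windows,
UTR/intron/flanking placement). The built-in classifier is deliberately
small: regulatory consequences, protein domains and HGVS synthesis are out
of scope.
"""

from __future__ import annotations

import logging
from typing import Callable, Optional, Sequence

from Bio.Seq import Seq

from .model import (
    AnnotationBundle,
    ClinVarAssertion,
    ClinVarSignificance,
    GenomicRegion,
    Impact,
    NormalizedVariant,
    VariantKey,
)
from .region_io import Transcript

logger = logging.getLogger(__name__)

ReferenceFetch = Callable[[GenomicRegion], str]

__all__ = [
    "IMPACT_TABLE",
    "SPLICE_WINDOW",
    "FLANK_BP",
    "parse_csq",
    "csq_format_from_header",
    "classify",
    "classify_gene",
]

#: Every consequence term the classifier can emit maps to exactly one impact.
IMPACT_TABLE: dict[str, Impact] = {
    "frameshift_variant": Impact.HIGH,
    "stop_gained": Impact.HIGH,
    "stop_lost": Impact.HIGH,
    "start_lost": Impact.HIGH,
    "splice_acceptor_variant": Impact.HIGH,
    "splice_donor_variant": Impact.HIGH,
    "missense_variant": Impact.MODERATE,
    "inframe_insertion": Impact.MODERATE,
    "inframe_deletion": Impact.MODERATE,
    "synonymous_variant": Impact.LOW,
    "intron_variant": Impact.MODIFIER,
    "5_prime_UTR_variant": Impact.MODIFIER,
    "3_prime_UTR_variant": Impact.MODIFIER,
    "upstream_gene_variant": Impact.MODIFIER,
    "downstream_gene_variant": Impact.MODIFIER,
    "intergenic_variant": Impact.MODIFIER,
    "non_coding_transcript_exon_variant": Impact.MODIFIER,
    "coding_sequence_variant": Impact.MODIFIER,
}

SPLICE_WINDOW = 2  # bp at each intron end (canonical donor/acceptor)
FLANK_BP = 1000    # up/downstream window; beyond it a variant is intergenic

_CLIN_SIG_CSQ = {
    "pathogenic": ClinVarSignificance.PATHOGENIC,
    "likely_pathogenic": ClinVarSignificance.LIKELY_PATHOGENIC,
    "uncertain_significance": ClinVarSignificance.UNCERTAIN,
    "likely_benign": ClinVarSignificance.LIKELY_BENIGN,
    "benign": ClinVarSignificance.BENIGN,
    "conflicting_interpretations_of_pathogenicity": ClinVarSignificance.CONFLICTING,
}


def csq_format_from_header(description: str) -> list[str]:
    """Subfield names from a CSQ header description
    ('... Format: Allele|Consequence|...')."""
    if "Format:" in description:
        description = description.split("Format:", 1)[1]
    return [f.strip().strip('"') for f in description.strip().split("|")]


def _bundle_from_entry(entry: dict[str, str]) -> AnnotationBundle:
    consequence = entry.get("Consequence", "").split("&")[0]
    impact_str = entry.get("IMPACT", "")
    impact = Impact[impact_str] if impact_str in Impact.__members__ else None
    if impact is None and consequence in IMPACT_TABLE:
        impact = IMPACT_TABLE[consequence]
    revel = entry.get("REVEL") or None
    dbsnp = next(
        (x for x in entry.get("Existing_variation", "").split("&") if x.startswith("rs")),
        None,
    )
    clinvar = None
    clin_sig = entry.get("CLIN_SIG", "").split("&")[0].lower()
    if clin_sig in _CLIN_SIG_CSQ:
        clinvar = ClinVarAssertion(significance=_CLIN_SIG_CSQ[clin_sig])
    return AnnotationBundle(
        consequence=consequence,
        impact=impact,
        revel=float(revel) if revel else None,
        hgvs_c=entry.get("HGVSc") or None,
        hgvs_p=entry.get("HGVSp") or None,
        dbsnp_id=dbsnp,
        clinvar=clinvar,
        transcript_id=entry.get("Feature") or None,
        gene=entry.get("SYMBOL") or None,
    )


def parse_csq(
    info_field: Optional[str], csq_format: Sequence[str]
) -> tuple[list[AnnotationBundle], AnnotationBundle]:
    """Per-transcript bundles from a CSQ INFO value, plus the canonical
    pick: the highest-impact transcript, ties broken by transcript id.

    Absent CSQ yields an empty list and an ``unannotated``-flagged bundle;
    entries with the wrong number of subfields are skipped with a warning.
    """
    if not info_field:
        return [], AnnotationBundle(flags=("unannotated",))
    bundles: list[AnnotationBundle] = []
    for raw in info_field.split(","):
        parts = raw.split("|")
        if len(parts) != len(csq_format):
            logger.warning(
                "malformed CSQ entry (%d fields, expected %d): %.60s",
                len(parts),
                len(csq_format),
                raw,
            )
            continue
        bundles.append(_bundle_from_entry(dict(zip(csq_format, parts))))
    if not bundles:
        return [], AnnotationBundle(flags=("unannotated",))
    canonical = min(
        bundles,
        key=lambda b: (
            b.impact if b.impact is not None else Impact.MODIFIER,
            b.transcript_id or "~",
        ),
    )
    return bundles, canonical


def _splice_hit(
    tx: Transcript, vstart: int, vend: int, overlaps
) -> Optional[str]:
    for istart, iend in tx.introns():
        if iend - istart < 2 * SPLICE_WINDOW:
            continue
        left = (istart, istart + SPLICE_WINDOW)
        right = (iend - SPLICE_WINDOW, iend)
        donor, acceptor = (left, right) if tx.strand == "+" else (right, left)
        if overlaps(*donor):
            return "splice_donor_variant"
        if overlaps(*acceptor):
            return "splice_acceptor_variant"
    return None


def classify(
    variant: NormalizedVariant | VariantKey,
    transcript: Transcript,
    reference_fetch: ReferenceFetch,
) -> tuple[str, Impact]:
    """Consequence term and impact of a normalized variant on one
    transcript."""
    key = variant.key if isinstance(variant, NormalizedVariant) else variant
    tx = transcript
    if key.contig != tx.contig:
        return "intergenic_variant", Impact.MODIFIER
    pos0 = key.pos - 1
    is_indel = len(key.ref) != len(key.alt)
    if is_indel:
        # anchored spelling: the event sits after the shared anchor base
        vstart = pos0 + 1
        vend = pos0 + len(key.ref) if len(key.ref) > len(key.alt) else pos0 + 1
    else:
        vstart, vend = pos0, pos0 + len(key.ref)

    def overlaps(s: int, e: int) -> bool:
        if vend > vstart:
            return vstart < e and vend > s
        return s < vstart < e  # zero-length insertion point strictly inside

    if vend <= tx.start - FLANK_BP or vstart >= tx.end + FLANK_BP:
        return "intergenic_variant", Impact.MODIFIER
    if vend <= tx.start:
        term = "upstream_gene_variant" if tx.strand == "+" else "downstream_gene_variant"
        return term, Impact.MODIFIER
    if vstart >= tx.end:
        term = "downstream_gene_variant" if tx.strand == "+" else "upstream_gene_variant"
        return term, Impact.MODIFIER

    splice = _splice_hit(tx, vstart, vend, overlaps)
    if splice:
        return splice, IMPACT_TABLE[splice]

    in_exon = any(overlaps(s, e) for s, e in tx.exons)
    if not in_exon:
        return "intron_variant", Impact.MODIFIER
    if not tx.cds:
        return "non_coding_transcript_exon_variant", Impact.MODIFIER

    cds_start, cds_end = tx.cds[0][0], tx.cds[-1][1]
    in_cds = any(overlaps(s, e) for s, e in tx.cds)
    if not in_cds:
        if vend <= cds_start or (vend == vstart and vstart <= cds_start):
            term = "5_prime_UTR_variant" if tx.strand == "+" else "3_prime_UTR_variant"
        else:
            term = "3_prime_UTR_variant" if tx.strand == "+" else "5_prime_UTR_variant"
        return term, Impact.MODIFIER

    if tx.cds_length % 3 != 0:
        logger.warning(
            "transcript %s CDS length %d not divisible by 3; region-level "
            "classification only",
            tx.id,
            tx.cds_length,
        )
        return "coding_sequence_variant", Impact.MODIFIER

    if is_indel:
        net = len(key.alt) - len(key.ref)
        if net % 3 != 0:
            return "frameshift_variant", Impact.HIGH
        term = "inframe_insertion" if net > 0 else "inframe_deletion"
        return term, IMPACT_TABLE[term]

    return _classify_substitution(key, tx, reference_fetch)


def _classify_substitution(
    key: VariantKey, tx: Transcript, reference_fetch: ReferenceFetch
) -> tuple[str, Impact]:
    """Protein-level effect of an equal-length substitution: build the
    reference and mutated spliced CDS, translate both, compare."""
    pos0 = key.pos - 1
    ref_parts: list[str] = []
    alt_parts: list[str] = []
    for s, e in tx.cds:
        seg = reference_fetch(GenomicRegion(tx.contig, s, e)).upper()
        mut = list(seg)
        for i, base in enumerate(key.alt):
            g = pos0 + i
            if s <= g < e:
                mut[g - s] = base
        ref_parts.append(seg)
        alt_parts.append("".join(mut))
    cds_ref = "".join(ref_parts)
    cds_alt = "".join(alt_parts)
    if tx.strand == "-":
        cds_ref = str(Seq(cds_ref).reverse_complement())
        cds_alt = str(Seq(cds_alt).reverse_complement())
    if cds_alt == cds_ref:  # substitution confined to non-CDS bases
        return "coding_sequence_variant", Impact.MODIFIER
    if cds_ref[:3] == "ATG" and cds_alt[:3] != "ATG":
        return "start_lost", Impact.HIGH
    prot_ref = str(Seq(cds_ref).translate())
    prot_alt = str(Seq(cds_alt).translate())
    if prot_ref == prot_alt:
        return "synonymous_variant", Impact.LOW
    for ref_aa, alt_aa in zip(prot_ref, prot_alt):
        if ref_aa == alt_aa:
            continue
        if alt_aa == "*":
            return "stop_gained", Impact.HIGH
        if ref_aa == "*":
            return "stop_lost", Impact.HIGH
        return "missense_variant", Impact.MODERATE
    return "missense_variant", Impact.MODERATE


def classify_gene(
    variant: NormalizedVariant | VariantKey,
    transcripts: Sequence[Transcript],
    reference_fetch: ReferenceFetch,
) -> tuple[str, Impact, Optional[Transcript]]:
    """Max-impact consequence over a gene's transcripts (the single badge
    shown per gene); ties broken by transcript id."""
    if not transcripts:
        return "intergenic_variant", Impact.MODIFIER, None
    results = [
        (classify(variant, tx, reference_fetch), tx) for tx in transcripts
    ]
    (term, impact), tx = min(results, key=lambda r: (r[0][1], r[1].id))
    return term, impact, tx
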