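"""Multi-allelic decomposition and left-align/trim normalization.

Annotation joins are only correct if both sides use one canonical spelling
per allele. This module enforces that: every record is split into
biallelic records, then each allele pair is reduced to its parsimonious,
left-aligned form by the classic normalization loop — iteratively truncate
shared terminal bases, extend left with reference sequence whenever an
allele empties, and finally trim shared leading bases while both alleles
exceed length one. Applying the procedure twice is the identity.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Callable, Iterable, Optional, Sequence

from .model import GenomicRegion, GenotypeCall, NormalizedVariant, VariantKey
from .region_io import VariantRecord

logger = logging.getLogger(__name__)

ReferenceFetch = Callable[[GenomicRegion], str]

__all__ = [
    "NormalizationError",
    "decompose",
    "left_align_trim",
    "normalize_all",
    "old_variant_tag",
]


class NormalizationError(ValueError):
    pass


def _is_symbolic(allele: str) -> bool:
    return allele.startswith("<") or "[" in allele or "]" in allele


def _remap_genotype(call: GenotypeCall, alt_index: int) -> GenotypeCall:
    """Project a genotype onto one alt: that alt becomes 1, other alts
    become missing, ref stays 0. Allele depths subset to (ref, this alt)."""

    def remap(a: Optional[int]) -> Optional[int]:
        if a is None or a == 0:
            return a
        return 1 if a == alt_index else None

    ad = call.allele_depths
    if ad is not None and len(ad) > alt_index:
        ad = (ad[0], ad[alt_index])
    else:
        ad = None
    return replace(
        call,
        alleles=tuple(remap(a) for a in call.alleles),
        allele_depths=ad,
        n_alleles=2,
    )


def _split_info(info: dict, alt_index: int, n_alts: int) -> dict:
    """Split per-alt (Number=A) and per-allele (Number=R) INFO arrays by
    position; scalars and other arrays are copied through."""
    out = {}
    for key, value in info.items():
        if isinstance(value, tuple):
            if len(value) == n_alts:
                out[key] = value[alt_index - 1]
                continue
            if len(value) == n_alts + 1:
                out[key] = (value[0], value[alt_index])
                continue
        out[key] = value
    return out


def decompose(record: VariantRecord) -> list[VariantRecord]:
    """One biallelic record per alt allele.

    Spanning-deletion alleles ('*') are dropped with a warning; symbolic
    alleles and breakends pass through flagged ``symbolic_unnormalized``.
    Records with malformed genotype indices are skipped with a warning.
    """
    n_alts = len(record.alts)
    if n_alts == 0:
        raise NormalizationError(f"record at {record.contig}:{record.pos} has no alt")
    if n_alts == 1 and not _is_symbolic(record.alts[0]):
        return [record]
    out: list[VariantRecord] = []
    for i, alt in enumerate(record.alts, start=1):
        if alt == "*":
            logger.warning(
                "dropping spanning-deletion allele at %s:%d", record.contig, record.pos
            )
            continue
        flags = record.flags
        if _is_symbolic(alt):
            flags = flags + ("symbolic_unnormalized",)
        try:
            genotypes = {
                s: _remap_genotype(g, i) for s, g in record.genotypes.items()
            }
        except ValueError as exc:
            logger.warning(
                "skipping record at %s:%d: malformed genotype (%s)",
                record.contig,
                record.pos,
                exc,
            )
            return []
        out.append(
            replace(
                record,
                alts=(alt,),
                info=_split_info(record.info, i, n_alts),
                genotypes=genotypes,
                flags=flags,
            )
        )
    return out


def left_align_trim(
    variant: VariantKey, reference_fetch: ReferenceFetch
) -> NormalizedVariant:
    """Reduce one allele pair to canonical form against the reference.

    SNVs pass through unchanged. The ref allele is checked against the
    reference sequence first; a mismatch raises naming the position and the
    expected base.
    """
    contig, pos, ref, alt = variant.contig, variant.pos, variant.ref, variant.alt
    expected = reference_fetch(
        GenomicRegion(contig, pos - 1, pos - 1 + len(ref))
    ).upper()
    if expected != ref:
        raise NormalizationError(
            f"ref allele {ref!r} at {contig}:{pos} does not match reference "
            f"({expected!r})"
        )
    # truncate shared terminal bases, extending left when an allele empties
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            if pos == 1:
                raise NormalizationError(
                    f"cannot left-extend past start of {contig} while "
                    f"normalizing {variant}"
                )
            base = reference_fetch(GenomicRegion(contig, pos - 2, pos - 1)).upper()
            ref, alt = base + ref, base + alt
            pos -= 1
    # trim shared leading bases while both alleles exceed length 1
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return NormalizedVariant(
        key=VariantKey(contig, pos, ref, alt), original=variant
    )


def old_variant_tag(original: VariantKey) -> str:
    return f"{original.contig}:{original.pos}:{original.ref}/{original.alt}"


def record_key(record: VariantRecord) -> VariantKey:
    if not record.is_biallelic:
        raise NormalizationError("record is not biallelic; decompose first")
    return VariantKey(record.contig, record.pos, record.ref, record.alts[0])


def _merge_duplicates(records: list[VariantRecord]) -> list[VariantRecord]:
    """Merge records identical after normalization; genotype disagreement
    keeps both, flagged ``conflicting_duplicates``."""
    merged: list[VariantRecord] = []
    for rec in records:
        if merged:
            prev = merged[-1]
            same = (prev.contig, prev.pos, prev.ref, prev.alts) == (
                rec.contig,
                rec.pos,
                rec.ref,
                rec.alts,
            )
            if same:
                conflict = any(
                    s in prev.genotypes
                    and prev.genotypes[s].alleles != g.alleles
                    for s, g in rec.genotypes.items()
                )
                if conflict:
                    merged[-1] = replace(
                        prev, flags=prev.flags + ("conflicting_duplicates",)
                    )
                    merged.append(
                        replace(rec, flags=rec.flags + ("conflicting_duplicates",))
                    )
                else:
                    genotypes = dict(prev.genotypes)
                    genotypes.update(rec.genotypes)
                    info = dict(rec.info)
                    info.update(prev.info)
                    merged[-1] = replace(prev, info=info, genotypes=genotypes)
                continue
        merged.append(rec)
    return merged


def normalize_all(
    records: Iterable[VariantRecord],
    reference_fetch: ReferenceFetch,
) -> list[VariantRecord]:
    """Decompose and normalize a region's records into coordinate-sorted
    biallelic records. Provenance (the pre-normalization spelling) is kept
    in the ``OLD_VARIANT`` INFO tag whenever normalization changed the
    record; duplicates arising from equivalent spellings are merged."""
    flat: list[VariantRecord] = []
    for record in records:
        for rec in decompose(record):
            if "symbolic_unnormalized" in rec.flags:
                flat.append(rec)
                continue
            key = record_key(rec)
            norm = left_align_trim(key, reference_fetch)
            if norm.key != key:
                info = dict(rec.info)
                info["OLD_VARIANT"] = old_variant_tag(key)
                rec = replace(
                    rec,
                    pos=norm.key.pos,
                    ref=norm.key.ref,
                    alts=(norm.key.alt,),
                    info=info,
                )
            flat.append(rec)
    flat.sort(key=lambda r: (r.contig, r.pos, r.ref, r.alts))
    return _merge_duplicates(flat)
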