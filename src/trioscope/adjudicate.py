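"""Allele-balance adjudication of candidate variants.

Allele balance — the ratio of alternate to (reference + alternate) read
observations — separates three recurring de novo situations: a genuinely
supported heterozygote whose balance is near 0.5 even at low depth; a
likely false positive whose balance is far too low for a heterozygote;
and an apparently-de-novo variant with alternate evidence in a parent,
suggesting it was inherited and the parental genotype is a false
negative. The numeric cutoffs are this package's documented defaults
(:class:`~trioscope.config.AdjudicationConfig`); they are pure
configuration and never alter the counts themselves.
"""

from __future__ import annotations

from typing import Optional

from .config import AdjudicationConfig
from .model import AdjudicationResult, AlleleCounts, GenotypeCall, Verdict

__all__ = ["allele_balance", "adjudicate_denovo", "genotype_consistency"]


def allele_balance(counts: AlleleCounts) -> Optional[float]:
    """alt / (ref + alt); None when no informative reads are present.
    ``other`` observations do not enter the ratio."""
    denom = counts.ref_obs + counts.alt_obs
    if denom == 0:
        return None
    return counts.alt_obs / denom


def adjudicate_denovo(
    proband: AlleleCounts,
    mother: AlleleCounts,
    father: AlleleCounts,
    config: AdjudicationConfig = AdjudicationConfig(),
) -> AdjudicationResult:
    """Review a genotype-classified de novo candidate against read
    evidence. Always returns a verdict:

    * ``insufficient_data`` — proband depth below ``min_depth_hard``;
    * ``likely_false_positive`` — proband allele balance below ``het_low``;
    * ``possibly_inherited`` — a parent shows at least ``parent_min_alt``
      alt reads making up at least ``parent_min_frac`` of its depth (both
      floors, so one stray read never triggers it);
    * ``supported`` otherwise, flagged ``low_coverage`` below
      ``low_cov_warn`` depth.
    """
    pab = allele_balance(proband)
    parent_ab = {
        "mother": allele_balance(mother),
        "father": allele_balance(father),
    }
    flags: list[str] = []
    if proband.depth < config.min_depth_hard or pab is None:
        return AdjudicationResult(
            Verdict.INSUFFICIENT_DATA, pab, parent_ab, ("low_depth",)
        )
    if pab < config.het_low:
        return AdjudicationResult(
            Verdict.LIKELY_FALSE_POSITIVE, pab, parent_ab, tuple(flags)
        )
    for name, counts in (("mother", mother), ("father", father)):
        frac = counts.alt_fraction
        if (
            counts.alt_obs >= config.parent_min_alt
            and frac is not None
            and frac >= config.parent_min_frac
        ):
            flags.append(f"alt_evidence_in_{name}")
    if flags:
        return AdjudicationResult(
            Verdict.POSSIBLY_INHERITED, pab, parent_ab, tuple(flags)
        )
    if proband.depth < config.low_cov_warn:
        flags.append("low_coverage")
    return AdjudicationResult(Verdict.SUPPORTED, pab, parent_ab, tuple(flags))


def genotype_consistency(
    call: GenotypeCall,
    counts: AlleleCounts,
    config: AdjudicationConfig = AdjudicationConfig(),
) -> tuple[str, ...]:
    """Flags where the called genotype disagrees with read evidence:
    het calls with allele balance outside [het_low, het_high], hom-alt
    calls below hom_alt_min, hom-ref calls with alt fraction above
    hom_ref_max."""
    flags: list[str] = []
    ab = allele_balance(counts)
    if call.is_het and ab is not None and not (config.het_low <= ab <= config.het_high):
        flags.append("ab_out_of_range_het")
    if call.is_hom_alt and ab is not None and ab < config.hom_alt_min:
        flags.append("ab_low_for_homalt")
    if call.is_hom_ref:
        frac = counts.alt_fraction
        if frac is not None and frac > config.hom_ref_max:
            flags.append("alt_evidence_in_homref")
    return tuple(flags)
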