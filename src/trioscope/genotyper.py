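"""On-demand site genotyping from pileups.

A single-sample, site-independent diploid genotyper under a binomial read
model: given a per-read error rate ``ε``, a read shows the alternate
allele with probability ε under genotype 0/0, 0.5 under 0/1 and 1−ε under
1/1. The posterior over the three genotypes (given priors) yields the
call and a phred-scaled quality −10·log10(1 − P(call)), capped at 99.

``call_region`` applies this model either to supplied candidate alleles
only (the analog of restricting an external caller to input alleles) or in
discovery mode, emitting sites whose pileup shows at least ``min_alt_obs``
alternate reads at allele balance at least ``min_ab``. Haplotype-aware
calling is deliberately out of scope; an external caller binary can be
passed through instead, preserving the same record contract.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from collections import Counter
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pysam
from scipy.special import logsumexp
from scipy.stats import binom

from .config import CallerConfig
from .model import AlleleCounts, GenomicRegion, GenotypeCall, VariantKey
from .normalize import normalize_all
from .region_io import PathLike, VariantRecord, fetch_reference, pileup_counts

__all__ = [
    "genotype_posteriors",
    "genotype_site",
    "call_region",
    "call_region_external",
    "ExternalCallerUnavailable",
    "ExternalOutputError",
]

MAX_QUALITY = 99.0

_GT_ALLELES = {"0/0": (0, 0), "0/1": (0, 1), "1/1": (1, 1)}


class ExternalCallerUnavailable(RuntimeError):
    pass


class ExternalOutputError(ValueError):
    pass


def genotype_posteriors(
    counts: AlleleCounts,
    error_rate: float = 0.01,
    priors: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
) -> np.ndarray:
    """Posterior P(0/0), P(0/1), P(1/1) given ref/alt read counts. The
    triple sums to 1; ``other`` observations are uninformative and ignored."""
    if not 0.0 < error_rate < 0.5:
        raise ValueError("error_rate must lie in (0, 0.5)")
    if abs(sum(priors) - 1.0) > 1e-9:
        raise ValueError("priors must sum to 1")
    n = counts.ref_obs + counts.alt_obs
    k = counts.alt_obs
    p_alt = np.array([error_rate, 0.5, 1.0 - error_rate])
    log_post = binom.logpmf(k, n, p_alt) + np.log(priors)
    return np.exp(log_post - logsumexp(log_post))


def genotype_site(
    counts: AlleleCounts,
    error_rate: float = 0.01,
    priors: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
) -> tuple[str, float]:
    """Maximum-posterior genotype and its phred-scaled quality. Zero
    informative depth yields a no-call ('./.', quality 0)."""
    if counts.ref_obs + counts.alt_obs == 0:
        return "./.", 0.0
    post = genotype_posteriors(counts, error_rate, priors)
    idx = int(np.argmax(post))
    p_err = 1.0 - post[idx]
    if p_err <= 10 ** (-MAX_QUALITY / 10):
        quality = MAX_QUALITY
    else:
        quality = min(MAX_QUALITY, -10.0 * np.log10(p_err))
    return ("0/0", "0/1", "1/1")[idx], float(quality)


def _record_for_site(
    key: VariantKey,
    counts: AlleleCounts,
    gt: str,
    quality: float,
    sample_id: str,
) -> VariantRecord:
    alleles = _GT_ALLELES.get(gt, (None, None))
    call = GenotypeCall(
        sample_id=sample_id,
        alleles=alleles,
        allele_depths=(counts.ref_obs, counts.alt_obs),
        depth=counts.depth,
        quality=quality,
    )
    return VariantRecord(
        contig=key.contig,
        pos=key.pos,
        ref=key.ref,
        alts=(key.alt,),
        qual=quality,
        info={"DP": counts.depth},
        genotypes={sample_id: call},
    )


def _discover_snvs(
    alignments: PathLike,
    refseq: str,
    region: GenomicRegion,
    config: CallerConfig,
) -> list[tuple[VariantKey, AlleleCounts]]:
    found: list[tuple[VariantKey, AlleleCounts]] = []
    with pysam.AlignmentFile(str(alignments)) as bam:
        for column in bam.pileup(
            region.contig,
            region.start,
            region.end,
            truncate=True,
            stepper="nofilter",
            min_base_quality=config.min_baseq,
            min_mapping_quality=config.min_mapq,
            ignore_overlaps=False,
        ):
            pos0 = column.reference_pos
            ref_base = refseq[pos0 - region.start]
            if ref_base == "N":
                continue
            bases: Counter[str] = Counter()
            for pr in column.pileups:
                aln = pr.alignment
                if aln.is_unmapped or aln.is_secondary or aln.is_qcfail:
                    continue
                if aln.is_duplicate and not config.count_duplicates:
                    continue
                if pr.is_del or pr.is_refskip:
                    continue
                bases[aln.query_sequence[pr.query_position].upper()] += 1
            ref_obs = bases.get(ref_base, 0)
            for base, alt_obs in bases.items():
                if base == ref_base or base == "N":
                    continue
                ab = alt_obs / (ref_obs + alt_obs)
                if alt_obs >= config.min_alt_obs and ab >= config.min_ab:
                    other = sum(bases.values()) - ref_obs - alt_obs
                    found.append(
                        (
                            VariantKey(region.contig, pos0 + 1, ref_base, base),
                            AlleleCounts(ref_obs, alt_obs, other),
                        )
                    )
    return found


def call_region(
    alignments: PathLike,
    reference: PathLike,
    region: GenomicRegion,
    candidate_sites: Optional[Sequence[VariantKey]] = None,
    config: CallerConfig = CallerConfig(),
    sample_id: str = "SAMPLE",
) -> list[VariantRecord]:
    """Genotype a region from one sample's alignments.

    With ``candidate_sites`` every candidate is genotyped and reported —
    including homozygous-reference outcomes. In discovery mode, SNV sites
    passing the emission thresholds are reported. Output records are
    normalized and coordinate-sorted, ready for the same annotation path
    as user-supplied variants.
    """
    sites: list[tuple[VariantKey, AlleleCounts]] = []
    if candidate_sites is not None:
        for key in candidate_sites:
            counts = pileup_counts(
                alignments,
                key.contig,
                key.pos,
                key.ref,
                key.alt,
                min_mapq=config.min_mapq,
                min_baseq=config.min_baseq,
                count_duplicates=config.count_duplicates,
            )
            sites.append((key, counts))
    else:
        refseq = fetch_reference(reference, region)
        sites = _discover_snvs(alignments, refseq, region, config)

    records = []
    for key, counts in sites:
        if counts.depth < config.min_coverage:
            continue
        gt, quality = genotype_site(counts, config.error_rate, config.priors)
        records.append(_record_for_site(key, counts, gt, quality, sample_id))

    def fetch(r: GenomicRegion) -> str:
        return fetch_reference(reference, r)

    return normalize_all(records, fetch)


#: Flag set used for the external caller pass-through.
FREEBAYES_FLAGS = [
    "--min-mapping-quality", "0",
    "--min-coverage", "0",
    "--use-duplicate-reads",
]


def call_region_external(
    freebayes_path: str,
    alignments: PathLike,
    reference: PathLike,
    region: GenomicRegion,
    candidate_vcf: Optional[PathLike] = None,
) -> list[VariantRecord]:
    """Invoke an external freebayes binary on a region, parse its VCF and
    normalize the result to the same record contract as the built-in
    caller."""
    binary = shutil.which(freebayes_path) or (
        freebayes_path if Path(freebayes_path).is_file() else None
    )
    if binary is None:
        raise ExternalCallerUnavailable(
            f"external caller unavailable ({freebayes_path!r} not found); "
            "use the built-in caller"
        )
    cmd = [binary, "-f", str(reference), "-r", str(region)] + FREEBAYES_FLAGS
    if candidate_vcf is not None:
        cmd += ["--only-use-input-alleles", "--variant-input", str(candidate_vcf)]
    cmd.append(str(alignments))
    proc = subprocess.run(cmd, capture_output=True, text=True, check=True)
    with tempfile.NamedTemporaryFile("w", suffix=".vcf", delete=False) as tmp:
        tmp.write(proc.stdout)
        tmp_path = tmp.name
    records: list[VariantRecord] = []
    try:
        with pysam.VariantFile(tmp_path) as vf:
            samples = list(vf.header.samples)
            for rec in vf:
                n_alleles = 1 + len(rec.alts or ())
                genotypes = {}
                for s in samples:
                    fmt = rec.samples[s]
                    gt = fmt.get("GT", (None,))
                    genotypes[s] = GenotypeCall(
                        sample_id=s,
                        alleles=tuple(gt) if gt is not None else (None,),
                        n_alleles=n_alleles,
                    )
                records.append(
                    VariantRecord(
                        contig=rec.contig,
                        pos=rec.pos,
                        ref=rec.ref,
                        alts=tuple(rec.alts or ()),
                        qual=rec.qual,
                        info=dict(rec.info),
                        genotypes=genotypes,
                    )
                )
    except (ValueError, OSError) as exc:
        raise ExternalOutputError(f"cannot parse external caller output: {exc}")
    finally:
        Path(tmp_path).unlink(missing_ok=True)

    def fetch(r: GenomicRegion) -> str:
        return fetch_reference(reference, r)

    return normalize_all(records, fetch)
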