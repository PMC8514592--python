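"""Region-scoped readers over indexed VCF, alignment, FASTA and gene-model
files, plus per-site pileup allele counting.

All access is streamed per region through htslib (pysam): tabix-style
fetches on VCF, indexed fetch/pileup on SAM/BAM, faidx slices on FASTA.
Remote streaming is out of scope; every locator is a local path.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import gffutils
import pysam

from .model import AlleleCounts, GenomicRegion, GenotypeCall

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

__all__ = [
    "VariantRecord",
    "Transcript",
    "GeneModels",
    "IndexRequiredError",
    "SampleNotFoundError",
    "ContigNotFoundError",
    "fetch_variants",
    "pileup_counts",
    "fetch_reference",
    "load_gene_models",
    "reverse_complement",
]


class IndexRequiredError(FileNotFoundError):
    pass


class SampleNotFoundError(KeyError):
    pass


class ContigNotFoundError(KeyError):
    pass


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class VariantRecord:
    """In-memory mirror of one VCF record (possibly multi-allelic)."""

    contig: str
    pos: int  # 1-based, VCF convention
    ref: str
    alts: tuple[str, ...]
    id: Optional[str] = None
    qual: Optional[float] = None
    filter: tuple[str, ...] = ()
    info: dict = field(default_factory=dict)
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)
    flags: tuple[str, ...] = ()

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1


def _require_index(path: PathLike) -> None:
    p = str(path)
    for ext in (".tbi", ".csi"):
        if os.path.exists(p + ext):
            return
    raise IndexRequiredError(
        f"{p} has no tabix index (.tbi/.csi); index it, e.g. with "
        f"`tabix -p vcf {p}`"
    )


def _genotype_from_sample(sample_id: str, fmt, n_alleles: int) -> GenotypeCall:
    gt = fmt.get("GT", (None,))
    alleles = tuple(gt) if gt is not None else (None,)
    ad = fmt.get("AD")
    if ad is not None and all(x is not None for x in ad):
        ad = tuple(int(x) for x in ad)
    else:
        ad = None
    dp = fmt.get("DP")
    gq = fmt.get("GQ")
    return GenotypeCall(
        sample_id=sample_id,
        alleles=alleles,
        phased=bool(getattr(fmt, "phased", False)),
        allele_depths=ad,
        depth=int(dp) if dp is not None else None,
        quality=float(gq) if gq is not None else None,
        n_alleles=n_alleles,
    )


def fetch_variants(
    vcf_path: PathLike,
    region: GenomicRegion,
    samples: Optional[Sequence[str]] = None,
) -> list[VariantRecord]:
    """All records overlapping ``region``, restricted to ``samples``
    (default: every sample in the header), in coordinate order.

    A record overlaps if any reference-aligned base does, so deletions
    spanning the region boundary are included (htslib fetch semantics).
    """
    _require_index(vcf_path)
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(vcf_path)) as vf:
        available = list(vf.header.samples)
        if samples is None:
            samples = available
        else:
            missing = [s for s in samples if s not in available]
            if missing:
                raise SampleNotFoundError(
                    f"samples {missing} not in VCF; available: {available}"
                )
        try:
            it = vf.fetch(region.contig, region.start, region.end)
        except ValueError:
            return []  # contig absent from this VCF: no records in region
        for rec in it:
            n_alleles = 1 + len(rec.alts or ())
            genotypes = {
                s: _genotype_from_sample(s, rec.samples[s], n_alleles)
                for s in samples
            }
            out.append(
                VariantRecord(
                    contig=rec.contig,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    id=rec.id,
                    qual=rec.qual,
                    filter=tuple(rec.filter.keys()),
                    info={k: v for k, v in rec.info.items()},
                    genotypes=genotypes,
                )
            )
    return out


def pileup_counts(
    alignments: PathLike,
    contig: str,
    pos: int,
    ref: str,
    alt: str,
    min_mapq: int = 0,
    min_baseq: int = 13,
    count_duplicates: bool = True,
) -> AlleleCounts:
    """Count reads supporting the ref, alt or any other allele at a site.

    ``pos`` is 1-based. For an insertion a read supports alt only if it
    carries the full inserted sequence immediately after the anchor base;
    for a deletion only if its alignment deletes exactly the ref suffix.
    Reads failing the mapping/base quality filters, and duplicates when
    ``count_duplicates`` is off, contribute to no category.
    """
    ref = ref.upper()
    alt = alt.upper()
    pos0 = pos - 1
    ref_obs = alt_obs = other_obs = 0
    with pysam.AlignmentFile(str(alignments)) as bam:
        if contig not in bam.references:
            raise ContigNotFoundError(
                f"contig {contig!r} absent from {alignments}"
            )
        for column in bam.pileup(
            contig,
            pos0,
            pos0 + 1,
            truncate=True,
            stepper="nofilter",
            min_base_quality=min_baseq,
            min_mapping_quality=min_mapq,
            ignore_overlaps=False,
        ):
            if column.reference_pos != pos0:
                continue
            for pr in column.pileups:
                aln = pr.alignment
                if aln.is_unmapped or aln.is_secondary or aln.is_qcfail:
                    continue
                if aln.is_duplicate and not count_duplicates:
                    continue
                if pr.is_refskip:
                    continue
                if pr.is_del:
                    other_obs += 1
                    continue
                qp = pr.query_position
                base = aln.query_sequence[qp].upper()
                if len(ref) == 1 and len(alt) == 1:  # SNV
                    if base == alt:
                        alt_obs += 1
                    elif base == ref:
                        ref_obs += 1
                    else:
                        other_obs += 1
                elif len(alt) > len(ref):  # insertion (anchored)
                    ins_len = len(alt) - len(ref)
                    inserted = aln.query_sequence[qp + 1 : qp + 1 + ins_len].upper()
                    if base == ref[0] and pr.indel == ins_len and inserted == alt[1:]:
                        alt_obs += 1
                    elif base == ref[0] and pr.indel == 0:
                        ref_obs += 1
                    else:
                        other_obs += 1
                else:  # deletion (anchored)
                    del_len = len(ref) - len(alt)
                    if base == ref[0] and pr.indel == -del_len:
                        alt_obs += 1
                    elif base == ref[0] and pr.indel == 0:
                        ref_obs += 1
                    else:
                        other_obs += 1
    return AlleleCounts(ref_obs=ref_obs, alt_obs=alt_obs, other_obs=other_obs)


def fetch_reference(fasta_path: PathLike, region: GenomicRegion) -> str:
    """Uppercase reference slice for ``region``; slices extending past the
    contig end come back truncated with a warning."""
    with pysam.FastaFile(str(fasta_path)) as fa:
        if region.contig not in fa.references:
            raise ContigNotFoundError(
                f"contig {region.contig!r} absent from {fasta_path}"
            )
        contig_len = fa.get_reference_length(region.contig)
        end = min(region.end, contig_len)
        if end < region.end:
            warnings.warn(
                f"region {region} extends past end of {region.contig} "
                f"({contig_len} bp); sequence truncated",
                stacklevel=2,
            )
        return fa.fetch(region.contig, region.start, end).upper()


@dataclass(frozen=True)
class Transcript:
    """One transcript model: exons and CDS segments in ascending genomic
    order (0-based half-open), regardless of strand."""

    id: str
    gene: str
    contig: str
    strand: str  # "+" or "-"
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for segs in (self.exons, self.cds):
            if any(s >= e for s, e in segs):
                raise ValueError("empty exon/CDS segment")
            if list(segs) != sorted(segs):
                raise ValueError("segments must be in ascending genomic order")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def coding_sequence(self, reference_fetch) -> str:
        """Spliced CDS in translation orientation. ``reference_fetch``
        maps a GenomicRegion to its sequence."""
        parts = [
            reference_fetch(GenomicRegion(self.contig, s, e)) for s, e in self.cds
        ]
        seq = "".join(parts)
        return reverse_complement(seq) if self.strand == "-" else seq

    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i][1] < self.exons[i + 1][0]
        )


@dataclass
class GeneModels:
    genes: dict[str, list[Transcript]]
    not_found: list[str]


def _transcripts_from_gff(path: str, wanted: set[str]) -> dict[str, list[Transcript]]:
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    found: dict[str, list[Transcript]] = {}
    for gene in db.features_of_type("gene"):
        names = set(gene.attributes.get("Name", [])) | set(
            gene.attributes.get("gene_name", [])
        ) | {gene.id}
        match = names & wanted
        if not match:
            continue
        gene_name = sorted(match)[0]
        for tx in db.children(gene, featuretype=("mRNA", "transcript"), order_by="start"):
            exons = tuple(
                sorted((f.start - 1, f.end) for f in db.children(tx, featuretype="exon"))
            )
            cds = tuple(
                sorted((f.start - 1, f.end) for f in db.children(tx, featuretype="CDS"))
            )
            found.setdefault(gene_name, []).append(
                Transcript(
                    id=tx.id,
                    gene=gene_name,
                    contig=tx.seqid,
                    strand=tx.strand,
                    start=tx.start - 1,
                    end=tx.end,
                    exons=exons or ((tx.start - 1, tx.end),),
                    cds=cds,
                )
            )
    return found


def _transcripts_from_bed12(path: str, wanted: set[str]) -> dict[str, list[Transcript]]:
    found: dict[str, list[Transcript]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"not BED12: {line[:60]!r}")
            contig, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            if name not in wanted:
                continue
            strand = f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                (start + off, start + off + size)
                for off, size in zip(offsets, sizes)
            )
            cds = tuple(
                (max(s, thick_start), min(e, thick_end))
                for s, e in exons
                if max(s, thick_start) < min(e, thick_end)
            )
            found.setdefault(name, []).append(
                Transcript(
                    id=name,
                    gene=name,
                    contig=contig,
                    strand=strand,
                    start=start,
                    end=end,
                    exons=exons,
                    cds=cds,
                )
            )
    return found


def load_gene_models(
    path: PathLike, gene_names: Iterable[str]
) -> GeneModels:
    """Resolve gene names against a local GFF3 or BED12 gene-model file.

    Unknown names are reported in ``not_found`` rather than raising;
    an all-unknown request returns an empty map plus the full warning list.
    """
    wanted = set(gene_names)
    p = str(path)
    if p.endswith((".bed", ".bed12")):
        found = _transcripts_from_bed12(p, wanted)
    else:
        found = _transcripts_from_gff(p, wanted)
    not_found = sorted(wanted - set(found))
    if not_found:
        logger.warning("gene names not found in %s: %s", p, ", ".join(not_found))
    return GeneModels(genes=found, not_found=not_found)
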