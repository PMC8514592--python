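"""Deterministic synthetic family-study data with planted scenarios.

Everything the pipeline consumes can be generated offline: a seeded
reference (two autosomal contigs and one chrX contig with planted genes),
GFF3 gene models, a quartet VCF, per-sample SAM/BAM alignments, a PED
file, and miniature ClinVar-style and gnomAD-style snapshot VCFs — plus a
JSON truth manifest listing every planted event with its expected
classification.

Scenarios model the recurring adjudication situations a reviewer meets:

* ``fig4a`` — low-depth heterozygous de novo: proband 10 ref / 6 alt
  reads, no parental alt evidence; supported despite 16x depth.
* ``fig4b`` — high-depth low-allele-balance candidate: 502 ref / 38 alt;
  a likely false positive.
* ``fig4c`` — parental alt evidence: proband 6 alt reads but each parent
  also carries 4; possibly inherited.
* ``fig4d`` — quartet Mendelian violation: sibling heterozygous under two
  homozygous-alternate parents.
* ``fig4e`` — empty VCF over a gene whose alignments carry five clear
  heterozygous SNVs, recoverable by the built-in caller.
* ``multiallelic``, ``homopolymer_indel`` — records exercising
  decomposition and left alignment.
* ``clinvar_hit``, ``common_af`` — variants matching packaged snapshot
  records.
* ``xlr`` — hemizygous chrX variant in a male proband with carrier mother.

Reads are 100 bp, ungapped, constant Q30, MAPQ 60; duplicates arise
naturally from offset cycling. This keeps every pileup auditable by hand.
The generator emulates none of the error structure of real sequencing
(no quality decay, mapping artifacts or strand bias).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam

__all__ = ["SCENARIOS", "SAMPLES", "generate", "write_snapshots", "FixtureGenerator"]

SAMPLES = ("proband", "mother", "father", "sibling")

READ_LENGTH = 100
BASE_QUALITY = chr(30 + 33)  # constant Q30
MAPQ = 60

_CONTIG_LENGTHS = {"chr1": 50_000, "chr2": 50_000, "chrX": 30_000}
_CONTIG_ORDER = ("chr1", "chr2", "chrX")

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSION = {"A": "C", "G": "T", "C": "A", "T": "G"}

_STOPS = {"TAA", "TAG", "TGA"}
_SAFE_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS | {"ATG"}
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class _Gene:
    name: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


_GENES = (
    _Gene(
        "GENE1", "chr1", "+",
        exons=((10_000, 10_200), (11_000, 11_300), (12_000, 12_200)),
        cds=((10_050, 10_200), (11_000, 11_300), (12_000, 12_150)),
    ),
    _Gene(
        "GENE2", "chr2", "-",
        exons=((20_000, 20_400), (20_600, 21_000)),
        cds=((20_100, 20_400), (20_600, 20_900)),
    ),
    _Gene(
        "GENEX", "chrX", "+",
        exons=((15_000, 15_600),),
        cds=((15_060, 15_360),),
    ),
)

#: planted scenario sites, 0-based
_SITE0 = {
    "fig4a": ("chr1", 10_100),
    "fig4b": ("chr1", 10_400),
    "fig4c": ("chr1", 11_100),
    "fig4d": ("chr1", 11_430),
    "multiallelic": ("chr1", 12_020),
    "clinvar_hit": ("chr1", 12_060),
    "common_af": ("chr1", 12_100),
    "xlr": ("chrX", 15_100),
}
_FIG4E_SITES0 = (20_150, 20_350, 20_550, 20_750, 20_950)
_HOMOPOLYMER_ANCHOR0 = 13_000  # chr1: 'A' then a C6 run then 'T'

#: read counts planted per scenario: sample -> (ref_obs, alt_obs)
_READ_PLAN = {
    "fig4a": {"proband": (10, 6), "mother": (30, 0), "father": (28, 0), "sibling": (20, 0)},
    "fig4b": {"proband": (502, 38), "mother": (40, 0), "father": (40, 0), "sibling": (40, 0)},
    "fig4c": {"proband": (10, 6), "mother": (26, 4), "father": (25, 4), "sibling": (20, 0)},
    "fig4d": {"proband": (0, 30), "mother": (0, 30), "father": (0, 28), "sibling": (15, 15)},
    "xlr": {"proband": (0, 20), "mother": (12, 10), "father": (20, 0), "sibling": (18, 0)},
}

SCENARIOS = (
    "fig4a", "fig4b", "fig4c", "fig4d", "fig4e",
    "multiallelic", "homopolymer_indel", "clinvar_hit", "common_af", "xlr",
)


class UnknownScenarioError(ValueError):
    def __init__(self, names: Iterable[str]):
        super().__init__(
            f"unknown scenario(s) {sorted(names)}; registry: {', '.join(SCENARIOS)}"
        )


class FixtureGenerator:
    """Seeded builder for the reference, genes and planted events. All
    randomness flows from one generator so outputs are byte-identical for
    a given seed."""

    def __init__(self, seed: int):
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self._sequences = {
            name: self.rng.choice(list("ACGT"), size=length)
            for name, length in _CONTIG_LENGTHS.items()
        }
        self._plant_genes()
        self._plant_homopolymer()
        self._seq_cache: dict[str, str] = {}

    # -- reference construction -------------------------------------------

    def _designed_cds(self, n_codons: int) -> str:
        """A valid CDS: ATG start, non-stop body, TAA stop. Codons 20 and
        21 are pinned to AAA and TGG so tests can plant synonymous /
        stop-gain substitutions at known coordinates."""
        body = list(self.rng.choice(_SAFE_CODONS, size=n_codons - 2))
        if n_codons > 22:
            body[19] = "AAA"
            body[20] = "TGG"
        return "ATG" + "".join(body) + "TAA"

    def _write_seq(self, contig: str, start: int, seq: str) -> None:
        arr = self._sequences[contig]
        arr[start : start + len(seq)] = list(seq)

    def _plant_genes(self) -> None:
        d600 = self._designed_cds(200)
        d300 = self._designed_cds(100)
        designed = {"GENE1": d600, "GENE2": d600, "GENEX": d300}
        for gene in _GENES:
            cds = designed[gene.name]
            genomic = cds if gene.strand == "+" else _revcomp(cds)
            offset = 0
            for s, e in gene.cds:
                self._write_seq(gene.contig, s, genomic[offset : offset + (e - s)])
                offset += e - s
            # canonical splice dinucleotides at intron ends
            for i in range(len(gene.exons) - 1):
                istart, iend = gene.exons[i][1], gene.exons[i + 1][0]
                if gene.strand == "+":
                    self._write_seq(gene.contig, istart, "GT")
                    self._write_seq(gene.contig, iend - 2, "AG")
                else:
                    self._write_seq(gene.contig, istart, "CT")
                    self._write_seq(gene.contig, iend - 2, "AC")

    def _plant_homopolymer(self) -> None:
        self._write_seq("chr1", _HOMOPOLYMER_ANCHOR0, "ACCCCCCT")

    def sequence(self, contig: str) -> str:
        if contig not in self._seq_cache:
            self._seq_cache[contig] = "".join(self._sequences[contig])
        return self._seq_cache[contig]

    def base(self, contig: str, pos0: int) -> str:
        return str(self._sequences[contig][pos0])

    # -- planted variant sites --------------------------------------------

    def site(self, name: str) -> dict:
        """Planted (contig, 1-based pos, ref, alt) for a single-site
        scenario."""
        contig, pos0 = _SITE0[name]
        ref = self.base(contig, pos0)
        return {"contig": contig, "pos": pos0 + 1, "ref": ref, "alt": _TRANSITION[ref]}

    def fig4e_sites(self) -> list[dict]:
        out = []
        for pos0 in _FIG4E_SITES0:
            ref = self.base("chr2", pos0)
            out.append(
                {"contig": "chr2", "pos": pos0 + 1, "ref": ref, "alt": _TRANSITION[ref]}
            )
        return out

    def multiallelic_alts(self) -> tuple[str, str]:
        contig, pos0 = _SITE0["multiallelic"]
        ref = self.base(contig, pos0)
        return _TRANSITION[ref], _TRANSVERSION[ref]

    # -- reads -------------------------------------------------------------

    def reads_for_site(
        self,
        scenario: str,
        sample: str,
        contig: str,
        pos0: int,
        alt: str,
        n_ref: int,
        n_alt: int,
    ) -> list[tuple[str, int, str]]:
        """(qname, 0-based start, sequence) triples; alt reads first.
        Offsets cycle so stacks deeper than the read length produce
        position-duplicate reads, which the pileup counts by default."""
        seq = self.sequence(contig)
        reads = []
        for i in range(n_ref + n_alt):
            offset = (i * 37) % READ_LENGTH
            start = min(max(0, pos0 - offset), len(seq) - READ_LENGTH)
            read = seq[start : start + READ_LENGTH]
            if i < n_alt:
                j = pos0 - start
                read = read[:j] + alt + read[j + 1 :]
            reads.append((f"{scenario}.{sample}.{i:04d}", start, read))
        return reads


# ---------------------------------------------------------------------------
# file writers


def _write_fasta(gen: FixtureGenerator, out_dir: Path) -> Path:
    path = out_dir / "ref.fa"
    with open(path, "w") as fh:
        for contig in _CONTIG_ORDER:
            fh.write(f">{contig}\n")
            seq = gen.sequence(contig)
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    pysam.faidx(str(path))
    return path


def _write_gff(out_dir: Path) -> Path:
    path = out_dir / "genes.gff3"
    lines = ["##gff-version 3"]
    for gene in _GENES:
        g1, g2 = gene.start + 1, gene.end
        lines.append(
            f"{gene.contig}\ttrioscope\tgene\t{g1}\t{g2}\t.\t{gene.strand}\t.\t"
            f"ID={gene.name};Name={gene.name}"
        )
        tx = f"{gene.name}-T1"
        lines.append(
            f"{gene.contig}\ttrioscope\tmRNA\t{g1}\t{g2}\t.\t{gene.strand}\t.\t"
            f"ID={tx};Parent={gene.name}"
        )
        for s, e in gene.exons:
            lines.append(
                f"{gene.contig}\ttrioscope\texon\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t"
                f"Parent={tx}"
            )
        cds_order = gene.cds if gene.strand == "+" else tuple(reversed(gene.cds))
        cumulative = 0
        phased = []
        for s, e in cds_order:
            phase = (3 - cumulative % 3) % 3
            phased.append((s, e, phase))
            cumulative += e - s
        for s, e, phase in sorted(phased):
            lines.append(
                f"{gene.contig}\ttrioscope\tCDS\t{s + 1}\t{e}\t.\t{gene.strand}\t{phase}\t"
                f"ID={tx}-cds;Parent={tx}"
            )
    path.write_text("\n".join(lines) + "\n")
    return path


def _write_ped(out_dir: Path) -> Path:
    path = out_dir / "family.ped"
    path.write_text(
        "FAM1\tfather\t0\t0\t1\t1\n"
        "FAM1\tmother\t0\t0\t2\t1\n"
        "FAM1\tproband\tfather\tmother\t1\t2\n"
        "FAM1\tsibling\tfather\tmother\t2\t1\n"
    )
    return path


def _write_sam_bam(
    gen: FixtureGenerator,
    out_dir: Path,
    reads_by_sample: dict[str, list[tuple[str, str, int, str]]],
) -> dict[str, str]:
    """Write per-sample SAM text, then derive coordinate-sorted, indexed
    BAM from it. Returns sample -> BAM path (relative)."""
    paths = {}
    order = {c: i for i, c in enumerate(_CONTIG_ORDER)}
    for sample in SAMPLES:
        reads = sorted(
            reads_by_sample.get(sample, []), key=lambda r: (order[r[1]], r[2], r[0])
        )
        sam_path = out_dir / f"{sample}.sam"
        with open(sam_path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:coordinate\n")
            for contig in _CONTIG_ORDER:
                fh.write(f"@SQ\tSN:{contig}\tLN:{_CONTIG_LENGTHS[contig]}\n")
            fh.write(f"@RG\tID:{sample}\tSM:{sample}\n")
            for qname, contig, start, seq in reads:
                fh.write(
                    f"{qname}\t0\t{contig}\t{start + 1}\t{MAPQ}\t{len(seq)}M\t*\t0\t0\t"
                    f"{seq}\t{BASE_QUALITY * len(seq)}\tRG:Z:{sample}\n"
                )
        bam_path = out_dir / f"{sample}.bam"
        pysam.sort("-o", str(bam_path), str(sam_path))
        pysam.index(str(bam_path))
        paths[sample] = bam_path.name
    return paths


def _vcf_header(samples: Sequence[str] = ()) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in _CONTIG_ORDER:
        header.contigs.add(contig, length=_CONTIG_LENGTHS[contig])
    if samples:
        header.formats.add("GT", 1, "String", "Genotype")
        header.formats.add("AD", "R", "Integer", "Allelic depths")
        header.formats.add("DP", 1, "Integer", "Read depth")
        header.formats.add("GQ", 1, "Integer", "Genotype quality")
        for s in samples:
            header.add_sample(s)
    return header


def _tabix(path: Path) -> Path:
    gz = pysam.tabix_index(str(path), preset="vcf", force=True, keep_original=True)
    return Path(gz)


def _write_family_vcf(
    out_dir: Path, records: list[dict]
) -> Path:
    """``records``: dicts with contig,pos (1-based),ref,alts,genotypes
    {sample: {"GT": tuple, "AD": tuple, "DP": int}}."""
    path = out_dir / "family.vcf"
    header = _vcf_header(SAMPLES)
    order = {c: i for i, c in enumerate(_CONTIG_ORDER)}
    records = sorted(records, key=lambda r: (order[r["contig"]], r["pos"]))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in records:
            rec = out.new_record(
                contig=r["contig"],
                start=r["pos"] - 1,
                alleles=(r["ref"],) + tuple(r["alts"]),
            )
            rec.qual = 100.0
            for sample in SAMPLES:
                fmt = r["genotypes"][sample]
                rec.samples[sample]["GT"] = fmt["GT"]
                if "AD" in fmt:
                    rec.samples[sample]["AD"] = fmt["AD"]
                if "DP" in fmt:
                    rec.samples[sample]["DP"] = fmt["DP"]
                rec.samples[sample]["GQ"] = fmt.get("GQ", 99)
            out.write(rec)
    return _tabix(path)


def write_snapshots(out_dir: str | Path, seed: int = 1) -> dict[str, str]:
    """Miniature indexed ClinVar-style and gnomAD-style snapshot VCFs
    consistent with the scenario registry (all records parsimonious and
    left-aligned, so normalization is a fixpoint on them)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gen = FixtureGenerator(seed)
    return _write_snapshots_with(gen, out_dir)


def _write_snapshots_with(gen: FixtureGenerator, out_dir: Path) -> dict[str, str]:
    clin = out_dir / "clinvar.vcf"
    header = _vcf_header()
    header.info.add("CLNSIG", ".", "String", "Clinical significance")
    header.info.add("CLNREVSTAT", ".", "String", "Review status")
    hit = gen.site("clinvar_hit")
    extra_sig = [
        (12_080, "Conflicting_interpretations_of_pathogenicity", "criteria_provided"),
        (12_090, "Benign", "reviewed_by_expert_panel"),
    ]
    with pysam.VariantFile(str(clin), "w", header=header) as out:
        rec = out.new_record(
            contig=hit["contig"], start=hit["pos"] - 1,
            alleles=(hit["ref"], hit["alt"]),
        )
        rec.info["CLNSIG"] = "Pathogenic"
        rec.info["CLNREVSTAT"] = "reviewed_by_expert_panel"
        out.write(rec)
        for pos0, sig, status in extra_sig:
            ref = gen.base("chr1", pos0)
            rec = out.new_record(
                contig="chr1", start=pos0, alleles=(ref, _TRANSITION[ref])
            )
            rec.info["CLNSIG"] = sig
            rec.info["CLNREVSTAT"] = status
            out.write(rec)
    clin_gz = _tabix(clin)

    gnomad = out_dir / "gnomad.vcf"
    header = _vcf_header()
    header.info.add("AF", "A", "Float", "Alternate allele frequency")
    header.info.add("nhet", "A", "Integer", "Heterozygote count")
    header.info.add("nhomalt", "A", "Integer", "Homozygous-alternate count")
    common = gen.site("common_af")
    multi_pos0 = 12_110
    multi_ref = gen.base("chr1", multi_pos0)
    with pysam.VariantFile(str(gnomad), "w", header=header) as out:
        rec = out.new_record(
            contig=common["contig"], start=common["pos"] - 1,
            alleles=(common["ref"], common["alt"]),
        )
        rec.info["AF"] = (0.12,)
        rec.info["nhet"] = (300,)
        rec.info["nhomalt"] = (20,)
        out.write(rec)
        rec = out.new_record(
            contig="chr1", start=multi_pos0,
            alleles=(multi_ref, _TRANSITION[multi_ref], _TRANSVERSION[multi_ref]),
        )
        rec.info["AF"] = (0.30, 0.007)
        rec.info["nhet"] = (100, 12)
        rec.info["nhomalt"] = (5, 1)
        out.write(rec)
    gnomad_gz = _tabix(gnomad)
    return {"clinvar": clin_gz.name, "gnomad": gnomad_gz.name}


# ---------------------------------------------------------------------------
# scenario assembly


def _hom(gt: str) -> dict:
    return {"GT": gt}


def _scenario_vcf_and_truth(gen: FixtureGenerator, name: str):
    """(vcf records, truth dict) for one scenario."""
    if name == "fig4e":
        sites = gen.fig4e_sites()
        return [], {
            "sites": sites,
            "expected": {"n_called": len(sites), "genotype": "0/1"},
        }

    if name == "multiallelic":
        contig, pos0 = _SITE0[name]
        ref = gen.base(contig, pos0)
        alt1, alt2 = _TRANSITION[ref], _TRANSVERSION[ref]
        record = {
            "contig": contig, "pos": pos0 + 1, "ref": ref, "alts": (alt1, alt2),
            "genotypes": {
                "proband": {"GT": (1, 2), "AD": (2, 8, 9), "DP": 19},
                "mother": {"GT": (0, 1), "AD": (10, 9, 0), "DP": 19},
                "father": {"GT": (0, 2), "AD": (11, 0, 8), "DP": 19},
                "sibling": {"GT": (0, 0), "AD": (20, 0, 0), "DP": 20},
            },
        }
        truth = {
            "site": {"contig": contig, "pos": pos0 + 1, "ref": ref, "alt": alt1},
            "expected": {
                "decomposed": [
                    {"alt": alt1, "proband_gt": "1/."},
                    {"alt": alt2, "proband_gt": "./1"},
                ]
            },
        }
        return [record], truth

    if name == "homopolymer_indel":
        anchor = _HOMOPOLYMER_ANCHOR0
        record = {
            "contig": "chr1", "pos": anchor + 5, "ref": "CC", "alts": ("C",),
            "genotypes": {
                "proband": {"GT": (0, 1), "AD": (12, 11), "DP": 23},
                "mother": {"GT": (0, 1), "AD": (14, 12), "DP": 26},
                "father": {"GT": (0, 0), "AD": (25, 0), "DP": 25},
                "sibling": {"GT": (0, 0), "AD": (22, 0), "DP": 22},
            },
        }
        truth = {
            "input": {"contig": "chr1", "pos": anchor + 5, "ref": "CC", "alt": "C"},
            "expected": {
                "normalized": {
                    "contig": "chr1", "pos": anchor + 1, "ref": "AC", "alt": "A",
                }
            },
        }
        return [record], truth

    site = gen.site(name)
    counts = _READ_PLAN.get(name)

    def fmt(sample: str, gt: tuple) -> dict:
        entry: dict = {"GT": gt}
        if counts and sample in counts:
            r, a = counts[sample]
            entry.update(AD=(r, a), DP=r + a)
        return entry

    genotype_plans = {
        "fig4a": {"proband": (0, 1), "mother": (0, 0), "father": (0, 0), "sibling": (0, 0)},
        "fig4b": {"proband": (0, 1), "mother": (0, 0), "father": (0, 0), "sibling": (0, 0)},
        "fig4c": {"proband": (0, 1), "mother": (0, 0), "father": (0, 0), "sibling": (0, 0)},
        "fig4d": {"proband": (1, 1), "mother": (1, 1), "father": (1, 1), "sibling": (0, 1)},
        "clinvar_hit": {"proband": (0, 1), "mother": (0, 1), "father": (0, 0), "sibling": (0, 0)},
        "common_af": {"proband": (0, 1), "mother": (0, 1), "father": (0, 1), "sibling": (0, 0)},
        "xlr": {"proband": (1,), "mother": (0, 1), "father": (0,), "sibling": (0, 0)},
    }
    gts = genotype_plans[name]
    record = {
        "contig": site["contig"], "pos": site["pos"], "ref": site["ref"],
        "alts": (site["alt"],),
        "genotypes": {s: fmt(s, gts[s]) for s in SAMPLES},
    }
    expected = {
        "fig4a": {"mode": "denovo", "verdict": "supported", "flags": ["low_coverage"]},
        "fig4b": {"mode": "denovo", "verdict": "likely_false_positive"},
        "fig4c": {"mode": "denovo", "verdict": "possibly_inherited"},
        "fig4d": {"violation_sample": "sibling"},
        "clinvar_hit": {"clinvar_significance": "pathogenic"},
        "common_af": {"af": 0.12, "het": 300, "hom": 20},
        "xlr": {"mode": "x_linked_recessive"},
    }[name]
    truth = {"site": site, "expected": expected}
    if counts:
        truth["counts"] = {s: list(counts[s]) for s in SAMPLES}
    truth["genotypes"] = {
        s: "/".join(str(a) for a in gts[s]) for s in SAMPLES
    }
    return [record], truth


def generate(
    scenario_set: Sequence[str],
    seed: int,
    out_dir: str | Path,
) -> dict:
    """Generate all files for the requested scenarios into ``out_dir``
    and return the manifest (also written as ``manifest.json``).

    Outputs are byte-identical for a given (scenario_set, seed).
    """
    unknown = set(scenario_set) - set(SCENARIOS)
    if unknown:
        raise UnknownScenarioError(unknown)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gen = FixtureGenerator(seed)

    vcf_records: list[dict] = []
    truths: dict[str, dict] = {}
    reads_by_sample: dict[str, list] = {s: [] for s in SAMPLES}

    for name in SCENARIOS:  # fixed order for determinism
        if name not in scenario_set:
            continue
        records, truth = _scenario_vcf_and_truth(gen, name)
        vcf_records.extend(records)
        truths[name] = truth
        if name in _READ_PLAN:
            site = gen.site(name)
            for sample, (n_ref, n_alt) in _READ_PLAN[name].items():
                for qname, start, seq in gen.reads_for_site(
                    name, sample, site["contig"], site["pos"] - 1,
                    site["alt"], n_ref, n_alt,
                ):
                    reads_by_sample[sample].append((qname, site["contig"], start, seq))
        elif name == "fig4e":
            for site in gen.fig4e_sites():
                plans = {"proband": (15, 15), "mother": (30, 0),
                         "father": (30, 0), "sibling": (30, 0)}
                for sample, (n_ref, n_alt) in plans.items():
                    for qname, start, seq in gen.reads_for_site(
                        name, sample, site["contig"], site["pos"] - 1,
                        site["alt"], n_ref, n_alt,
                    ):
                        reads_by_sample[sample].append(
                            (qname, site["contig"], start, seq)
                        )

    fasta = _write_fasta(gen, out_dir)
    gff = _write_gff(out_dir)
    ped = _write_ped(out_dir)
    vcf_gz = _write_family_vcf(out_dir, vcf_records)
    bam_paths = _write_sam_bam(gen, out_dir, reads_by_sample)
    snapshots = _write_snapshots_with(gen, out_dir)

    manifest = {
        "seed": seed,
        "scenarios": truths,
        "samples": list(SAMPLES),
        "proband": "proband",
        "genes": {
            g.name: {
                "contig": g.contig, "strand": g.strand,
                "start": g.start, "end": g.end,
            }
            for g in _GENES
        },
        "files": {
            "reference": fasta.name,
            "gff": gff.name,
            "ped": ped.name,
            "vcf": vcf_gz.name,
            "clinvar": snapshots["clinvar"],
            "gnomad": snapshots["gnomad"],
            "alignments": bam_paths,
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
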