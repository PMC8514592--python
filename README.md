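# trioscope

Desk-scale variant interrogation for family sequencing studies (trio or
quartet exome/genome data). In rare-disease analysis the candidate list for a
proband is worked through gene by gene: variants must be normalized so
annotation joins are reliable, classified by functional consequence, matched
against population (gnomAD-style) and clinical (ClinVar-style) snapshots,
segregated against the pedigree, and — for de novo candidates in particular —
checked against the raw read evidence, because genotype calls alone routinely
produce false positives and false negatives at exactly the variants that
matter most.

`trioscope` packages that workflow as a Python library plus a CLI over
standard formats: indexed VCF, SAM/BAM, FASTA, GFF3/BED12, PED, and plain
gene lists. Everything runs locally on region-scoped streams (gene
coordinates ± 1000 bp); no services, no uploads.

## What it computes

**Canonical variant keys.** Multi-allelic records are decomposed (one record
per alt; genotype indices remapped, other alts becoming missing) and each
allele pair is reduced by the classic normalization loop: truncate shared
terminal bases, extend left with reference sequence when an allele empties,
then trim shared leading bases. The resulting key `(contig, pos, ref, alt)`
is parsimonious and left-aligned, so any equivalent spelling of an indel
joins to the same annotation.

**Allele balance and de novo adjudication.** For read counts `(r, a)` at a
site, allele balance is `AB = a / (r + a)`. A genotype-classified de novo
candidate is adjudicated from the trio's pileups:

- `AB < 0.20` in the proband → **likely_false_positive** (the balance is far
  too low for a true heterozygote);
- a parent with ≥ 2 alt reads making up ≥ 2% of its depth →
  **possibly_inherited** (the parental hom-ref genotype is suspect);
- proband depth < 5 → **insufficient_data**;
- otherwise **supported**, flagged `low_coverage` below 20× — low depth with
  sound balance is evidence *for* a variant, not against it.

**Inheritance.** Per-variant segregation over the pedigree: de novo
(alt in the child, both parents called 0/0), autosomal recessive, X-linked
recessive (hemizygous males), autosomal dominant (carrier status tracking
affected status), plus Mendelian-violation detection — a child genotype that
no choice of one transmitted allele per parent can produce.

**Genotyping.** An on-demand single-sample binomial genotyper: a read shows
the alt allele with probability ε under 0/0, ½ under 0/1, 1−ε under 1/1; the
posterior over genotypes gives the call and a phred quality
`−10·log₁₀(1 − P(call))` capped at 99. Discovery mode emits sites with ≥ 3
alt reads at AB ≥ 0.10; candidate mode genotypes exactly the supplied
alleles. An external `freebayes` binary can be passed through instead.

**Ranking.** A deterministic six-level sort: review status, clinical
assertion (pathogenic → benign, with "no assertion" between uncertain and
likely benign), inheritance mode, impact, population allele frequency
("never observed" rarest of all), genomic coordinates. Analyses round-trip
losslessly through CSV or VCF export/import, including free-text notes.

## Worked example

All inputs can be generated offline with planted truths:

```
$ trioscope simulate --scenarios fig4a,fig4b,fig4c --seed 1 --out demo
{"out": "demo", "scenarios": ["fig4a", "fig4b", "fig4c"]}

$ trioscope adjudicate \
    --bam proband=demo/proband.bam --bam mother=demo/mother.bam \
    --bam father=demo/father.bam --site chr1:10101:T:C
{"verdict": "supported", "proband_ab": 0.375, "flags": ["low_coverage"],
 "counts": {"proband": [10, 6, 0], "mother": [30, 0, 0], "father": [28, 0, 0]}}
```

The proband pileup at the planted site shows 10 reference and 6 alternate
reads (16× total): balance 0.375 is squarely heterozygous, neither parent
carries an alt read, so the de novo candidate is **supported** — the depth
earns only a warning flag. The `fig4b` scenario (502 ref / 38 alt, AB ≈ 0.07)
adjudicates as `likely_false_positive`, and `fig4c` (each parent with 4 alt
reads) as `possibly_inherited`.

The full pipeline — normalization, consequence, snapshot joins, inheritance,
adjudication, ranking, CSV+VCF export — runs per gene:

```
$ trioscope analyze --vcf demo/family.vcf.gz --ped demo/family.ped \
    --ref demo/ref.fa --gff demo/genes.gff3 --gene GENE1 \
    --clinvar demo/clinvar.vcf.gz --gnomad demo/gnomad.vcf.gz \
    --bam proband=demo/proband.bam --bam mother=demo/mother.bam \
    --bam father=demo/father.bam --out results/
```

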