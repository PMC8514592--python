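# Methods

## Scope and model

`trioscope` re-implements, as a library, the computational core of
interactive family-variant review: region-scoped extraction, canonical
normalization, annotation joining, pedigree segregation, read-evidence
adjudication, coverage summarization, on-demand genotyping, and
deterministic prioritization. It operates on small (SNV/indel) variants in
diploid genomes with hemizygous handling of chrX/chrY in males; structural
variants, mitochondrial inheritance, compound-heterozygote pairing,
imprinting and mosaicism are out of scope.

Coordinates are 0-based half-open everywhere inside the library; the VCF
convention (1-based) appears only on `VariantKey` and at the I/O boundary.
Sex chromosomes are recognized by the aliases `X`/`chrX`, `Y`/`chrY`.
Without an explicit PAR definition, the whole X is treated as hemizygous in
males — the conservative default; supplying PAR intervals and treating them
as autosomal is a caller-side choice.

## Normalization

Every record is decomposed into biallelic records (genotype indices for the
current alt map to 1, other alts to missing; allele-depth vectors and
per-alt INFO arrays are subset by position; spanning-deletion `*` alleles
are dropped with a warning; symbolic alleles pass through flagged). Each
allele pair is then reduced by the standard left-align/trim loop:

1. while ref and alt share their last base, truncate it; if an allele
   empties, prepend the reference base to the left and decrement pos;
2. finally, while both alleles exceed length 1 and share their first base,
   drop it and increment pos.

The output is parsimonious (no shared terminal base; no shared leading base
while both alleles exceed length 1) and left-aligned; applying the procedure
twice is the identity. Note the left-most form of an indel inside a
homopolymer run is *anchored on the base preceding the run* — a one-base C
deletion in `A CCCCCC T` normalizes to `(pos_of_A, AC, A)`, not to a spelling
starting inside the run, which would still share a terminal base. The test
suite certifies this against a spelling-enumeration oracle (equivalence =
identical edited reference string) and against `bcftools norm` as an
independent implementation.

Records that become identical after normalization are merged; if merged
records disagree on a sample's genotype, both are kept and flagged
`conflicting_duplicates`. Pre-normalization spellings are preserved in the
`OLD_VARIANT` INFO tag.

## Pileup counting

`pileup_counts` classifies each read overlapping a site as supporting the
reference allele, the alternate, or *other*. SNVs compare the aligned base;
an insertion is supported only by reads carrying exactly the inserted
sequence after the anchor base; a deletion only by reads whose alignment
deletes exactly the reference suffix. Defaults: mapping quality ≥ 0 and no
coverage floor (mirroring the permissive settings of the upstream caller
this feature stands in for), base quality ≥ 13 (the common pileup default —
the displayed-count cutoffs were otherwise unspecified), duplicates counted
(a flag excludes them). `other` observations never enter allele balance but
do count toward depth.

## Adjudication thresholds

The three canonical de novo situations are separated by pure-configuration
cutoffs (section `[adjudication]`): `het_low = 0.20` / `het_high = 0.80`
(plausible heterozygous balance band), `parent_min_alt = 2` with
`parent_min_frac = 0.02` (both floors must be met, so a single stray
parental read never suggests inheritance), `min_depth_hard = 5` (below which
no verdict is meaningful), `low_cov_warn = 20` (a supported verdict below
this depth carries a `low_coverage` flag rather than being rejected — the
whole point of balance-based review is rescuing sound low-depth variants).
The source scenarios are described visually, without numeric cutoffs; these
defaults are this package's documented choices, set so that balance 0.375 at
16× is supported, 0.07 at 540× is a likely false positive, and 4 alt reads
(~13–14%) in each parent indicates possible inheritance. Verdicts are
monotone in proband allele balance by construction.

## Inheritance

De novo requires an alt in the proband with both parents *called*
homozygous reference; a missing parental genotype degrades to unknown with
reason "possible denovo, parent uncalled" rather than asserting de novo.
Autosomal recessive requires a hom-alt proband, two het parents, and no
unaffected sibling hom-alt. X-linked recessive covers hemizygous/hom-alt
males with a carrier (het) mother and non-carrier father, and hom-alt
females with carrier mother and hemizygous-alt father. Autosomal dominant
requires the het proband's carrier status to track affected status exactly
across called samples *and* an affected carrier other than the proband: in a
proband-only-affected trio a lone het child under a het unaffected parent is
reported unknown, not dominant — dominant calls without segregation
information would flood the output. X-linked dominant patterns are reported
as unknown. Male heterozygous calls on chrX are flagged as likely genotyping
artifacts.

Violation detection enumerates transmissions: a trio violates iff no choice
of one allele from each parent (single maternal allele for male-X; paternal
for chrY) yields the child genotype. A de novo-patterned proband record is
classified de novo, never as a violation; any other violating genotype
yields mode unknown with the violation flagged and explained.

## Genotyper

A site-independent diploid binomial model: alt-read probability ε (default
0.01) under 0/0, 0.5 under 0/1, 1−ε under 1/1, with configurable priors
(default flat). Quality is `−10·log₁₀(1 − posterior)` capped at 99; zero
informative depth yields a no-call. Discovery mode emits SNV sites with
`alt_obs ≥ 3` and `AB ≥ 0.10`; candidate mode reports *every* supplied
allele, including 0/0 outcomes, and supports indels through exact-match
pileup evidence. This is deliberately not a haplotype-aware caller; the
external-binary pass-through preserves that interface where a real caller
is available.

## Ranking and round trip

The sort tuple is (review status; clinical assertion with "no assertion"
ranked between uncertain and likely benign; inheritance mode; impact;
population AF ascending with "not observed" first; contig, pos, ref, alt).
Missing components rank last within their tier, making the order total.
"Poor quality" ranks below "Not significant"; review-status precedence over
the other keys is the package's documented choice. CSV export is RFC-4180
with a mandatory header; VCF export declares String-typed INFO tags with
free text percent-encoded, so byte-exact round trips hold for every exported
field (floats are serialized with full precision; joined allele frequencies
are rounded to 6 decimals once, at join time, to undo htslib's
single-precision INFO storage).

## Synthetic data

The fixture generator emulates a quartet study over a seeded reference
(two 50 kb autosomal contigs plus a 30 kb chrX) with three planted genes,
including a minus-strand gene carrying the same designed CDS as the
plus-strand one (enabling strand-symmetry checks; codons 20/21 are pinned to
AAA/TGG so synonymous and stop-gain edits have known coordinates). Reads are
100 bp, ungapped, constant Q30, MAPQ 60, tiled by cycling offsets — pileups
are auditable by hand, and stacks deeper than the read length naturally
contain position-duplicates. Planted scenarios cover the three adjudication
cases (10/6 at 16×; 502/38; 6 alt with 4 alt in each parent — parental
counts 30/0, 28/0, 26/4, 25/4 where only the 4-alt figure is externally
specified), a quartet Mendelian violation, a gene with an empty VCF but five
callable het SNVs at depth ≥ 20, a tri-allelic site, a right-shifted
homopolymer deletion, snapshot-matching variants (pathogenic assertion;
AF 0.12 with 300 het / 20 hom-alt carriers), and a hemizygous male chrX
case. Snapshot records are normalization fixpoints by construction.

What passing on this data does *not* show: robustness to mapping artifacts,
strand bias, quality decay, contamination, or low-complexity alignment
ambiguity — the generator has no error model beyond planted counts.

## Numerical and degenerate-input choices

Median of an even-length depth profile is the mean of the two central order
statistics. Empty profiles and empty regions are errors; a region past the
contig end is truncated with a warning. Allele balance is undefined (not 0)
at zero informative depth, and "absent from the population snapshot" is
distinct from AF = 0 — it ranks rarer than any numeric frequency.
Normalization refuses to run off the start of a contig. CDS lengths not
divisible by 3 limit classification to a region-level term
(`coding_sequence_variant`). The splice window is the 2 bp canonical
donor/acceptor dinucleotide at each intron end; up/downstream extends
1000 bp from the transcript, beyond which a variant is intergenic. When a
variant hits several transcripts, the per-gene badge is the most severe
(max-impact) consequence, ties broken by transcript id — transcript
selection rules differ between tools and this deterministic choice is
documented rather than configurable.

## Problem sizes

Tests and the acceptance script run on the generated fixtures: ≤ 50 kb
contigs, hundreds of reads per site (540 at the deepest planted pileup),
10⁴ fuzzed variants for the normalization properties, 100 randomized
export/import analyses, and 2×10³ fuzzed count pairs for the genotyper
properties — sizes chosen so every check is exact and the whole suite runs
in seconds.
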