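# Methods

## Scope and model

The toolkit implements a gene-centred polymorphism workflow for inbred
resequencing comparisons: consensus calling from pileups, codon-level
functional classification against gene models, and aggregation into
gene/chromosome/family tables. Read mapping, base-quality recalibration and
genotype-likelihood models are out of scope; the pileup is the entry point
and is assumed to carry per-read base, Phred-like quality (0–40), a
unique-mapping flag and optional indel evidence.

## Coordinates and formats

All coordinates are 1-based inclusive (GFF3/VCF native); no half-open
convention is exposed. The pileup dialect is a documented TSV
(`chrom  pos  ref  BASE:QUAL:FLAG[:+SEQ|-SEQ],...`) inspired by
`samtools mpileup` but self-contained, since the upstream caller's internal
files are not a public format. VCF output is site-only (no genotypes) with
INFO keys VT/SUP/CONC/ZY; call concordances are stored rounded to six
decimals so that writing and re-reading a call list is exact. GFF3 parsing
goes through gffutils; when a gene has several mRNAs the representative
transcript is the one with the longest total CDS (ties: lexicographically
smallest transcript id), because all tables count per locus, not per
isoform. When explicit UTR features are absent, UTRs are derived as
exon-minus-CDS split at the CDS genomic extent and assigned 5′/3′ roles by
strand.

## Consensus caller

Per site, in order: observations with quality < 5 are masked; the majority
base is taken (a tied majority means no consensus and the site goes to the
heterozygous channel); support counts only unique-mapping reads carrying
the majority base, while concordance is majority-count over all surviving
observations (the alternative of excluding non-unique reads from the
denominator is not documented upstream; we use the inclusive denominator).
A site is heterozygous when the minority fraction reaches `het_minority`
(default 0.25). A homozygous variant call requires majority ≠ reference,
concordance ≥ 0.80, support ≥ 3 and quality > 25 (strict, per the
"more than 25 out of 40" convention).

The 0–40 site quality has no published closed form computable from pileup
evidence, so the package defines
`quality = round(40 · concordance · min(1, support/min_support))`, clipped
to [0, 40]. This preserves the scale, makes quality monotone in both
evidence quantities, and reduces to `40·concordance` once support is
saturated — with the default thresholds a call passing concordance and
support always scores ≥ 32, so the quality cutoff binds only under
non-default configurations. The chastity score (Illumina cluster purity,
0.5–1.0) is an image-analysis quantity that cannot be recomputed from
pileups; it is retained as a pass-through configuration field documented as
upstream-only. InDels are called by exact string match of indel evidence:
a call requires the identical `+SEQ`/`-SEQ` on ≥ 3 unique reads making up
≥ 80% of all reads at the site — the simplest rule consistent with the SNP
filters; at most one indel can exceed a 50% concordance bar, so the rule is
unambiguous. Sites with reference base N are logged and skipped.

## Effect annotation

Region classification per overlapping locus uses precedence CDS > UTR
> intron/non-coding within a gene; a variant overlapping no gene is
intergenic. Each variant additionally carries a single genome-wide primary
category chosen by precedence cds > utr5 > utr3 > intron_noncoding >
intergenic across its loci — overlapping-gene handling is not specified by
any published rule, and cds-first retains the most functional information.
Per-locus records (used for gene tables) and primary categories (used for
genome-wide tables) are kept separately so both conventions can be read
off.

Codon classification splices CDS segments in genomic order,
reverse-complements for minus-strand genes, substitutes the single
alternate base and translates ref and alt codons with the standard nuclear
genetic code. Multiple SNPs hitting one codon are evaluated independently
against the reference codon (counts are per-SNP; haplotype-aware codon
reconstruction is out of scope). Stop-gained and stop-lost are counted
inside the non-synonymous total, which is what makes synonymous +
non-synonymous equal the CDS count in every table. A CDS whose annotated
length is not divisible by 3 is flagged; variants in its complete codons
annotate normally and a variant in the trailing partial codon is recorded
as intron/non-coding (located but not codon-classifiable) and logged. The
annotator is validated against an independent oracle — full-CDS
retranslation and whole-protein comparison via Biopython — over every
single-base substitution of randomly generated genes on both strands.

## Summaries

Ka and Ks are raw substitution counts per locus (Ka = missense +
stop_gained + stop_lost, Ks = synonymous); the ratio is undefined when
Ks = 0 rather than infinite, so screens for Ka/Ks > 1 must treat undefined
separately. An optional Nei–Gojobori-style per-site mode
(`ka_ks_normalized`) divides the counts by the gene's non-synonymous and
synonymous site totals; it is offered for users who expect per-site rates
and is not used in the main tables. Hotspots are loci with strictly more
than 100 SNPs (the range-bin table keeps "96–100" and ">100" separate,
which fixes the strict inequality). Percentages are reported rounded
half-up to whole percent and densities to one decimal, matching the
reporting style of the tables the package mirrors. The totals row of a
chromosome table is always computed by summation; `validate_printed_totals`
compares computed sums against an externally printed totals row and flags
disagreements (the packaged table's insertion/deletion grand totals exceed
their column sums by ~6–7 k; all SNP columns sum exactly). The "top third"
genic-share statistic ranks SNP-carrying genes by count with ties at the
cut broken by locus id — a deterministic choice where no tie rule is
published. Per-chromosome covered kb must be supplied by the user for
densities, since coverage comes from mapping, which is out of scope.

## Synthetic data

The generator emulates an inbred-vs-reference comparison at desk scale.
Defaults: 2 chromosomes × 250 kb, 0.1 genes/kb (~50 genes), 2–5 exons per
gene, equal strand mix, CDS of 100–300 codons (ATG + sense codons + one
terminal stop, no internal in-frame stop, length divisible by 3), UTRs of
100–300 bases, introns of 100–400 bases, uniform base composition and no
repeat structure (repeat handling belongs to mapping, upstream of the
pileup). SNP rates are per kb of each category's own territory —
intergenic 3.0, intron 3.0, UTRs 3.0, CDS-synonymous 2.5, CDS-missense
3.5, stop-gained 0.3 per CDS-kb, stop-lost 0.1 per gene (one stop codon is
available per gene) — yielding ≈ 1,700 planted variants on the default
genome, a density of the same order as real inter-subspecies rice
comparisons while keeping genic categories well populated. InDels (1–3 bp,
0.3/kb) and a configurable heterozygous fraction complete the truth set.
Every coding plant is verified at planting time by full-CDS retranslation,
so the truth set cannot disagree with its own labels. Per-category plant
counts are rounded deterministically at chromosome scale and
stochastically at per-gene scale (keeping small expectations unbiased).

Pileups are emitted at every planted site plus background non-variant
sites at 20/kb rather than at every genomic base — base-resolution columns
over half a megabase add bulk but no information to recovery checks, and
false positives can only arise at emitted columns. Depth defaults to 20
with sequencing-error rate 0 and heterozygous fraction 0 (the noise-free
homozygous condition under which exact recovery is asserted); correct
bases draw qualities in [25, 40] with a 2% tail below the masking cutoff,
and 98% of reads are unique-mapping (see `SimulationConfig` for the exact
fields). Heterozygous sites draw their alternate-read
count from a Binomial(depth, 0.5) conditioned on both alleles holding at
least 30% of reads: an unconditioned binomial would occasionally (p ≈ 0.6%
per site at depth 20) produce an allele balance that is legitimately
homozygous-looking, and the generator's contract is that every planted het
is unambiguously heterozygous at the configured depth for any seed. This
means the simulator does not model extreme allelic sampling noise, and
passing het-exclusion tests say nothing about such sites in real data.

All randomness derives from one mandatory seed through three per-stage
child streams (genome, planting, pileup), so each stage is reproducible in
isolation and identical seeds give byte-identical FASTA/GFF3/pileup files.

## What passing tests do and do not show

Exact recovery (sensitivity = precision = 1, categories equal truth)
holds under the noise-free homozygous study conditions; it validates the
threshold logic, coordinate arithmetic and codon classification, not
robustness to mapping artefacts, repeats, indel realignment or real error
profiles, none of which the simulator models. The packaged per-chromosome
table exercises the arithmetic of the summary layer only — genome-scale
counts from the real 108M-read comparison require the mapping stage and
are deliberately not reproduced here.

## Problem sizes

Default validation sizes: 20 oracle genes × 2,700 substitutions (~54,000
codon checks), a 500 kb recovery study with ~1,700 planted variants at
depth 20 (~12,000 pileup columns), and a 2 × 60 kb study for the
session-level pipeline tests. These run in seconds and were chosen as the
smallest sizes at which every category (including stop-lost, the rarest)
is reliably populated.
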