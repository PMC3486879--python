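# Methods

## Overview

`exonskip` implements an analysis linking intronic single-nucleotide variants
to alternative splicing and, ultimately, to complex-trait genetics. The chain
of reasoning is: an intronic splicing enhancer (ISE) is a short intronic
cis-element — modeled here as an exact hexamer — that promotes inclusion of an
adjacent exon; a SNP falling inside such a hexamer can create or destroy the
element; if the adjacent exon is a cassette exon (present in some isoforms,
absent in others), the variant is a candidate regulator of exon skipping; and
if skipping variants matter for phenotypes, they should be over-represented
among trait-associated SNPs beyond what their allele-frequency and positional
properties predict. Each arrow in that chain is one module, and the package is
exercised end-to-end on synthetic data whose ground truth is known.

## Motif scanning

For a SNP at position *p* we take `flank = 5` bases on each side, producing an
11-mer with the variant base at the center. The 11-mer is fragmented into the
six hexamer frames that contain the variant base, starting with the SNP in the
last position of the frame and shifting the frame upstream one base at a time
until the SNP is in the first position. A frame matches only by exact string
equality with a motif in the set; frames touching `N` padding (contig edges)
never match. Both alleles are always scanned, and a SNP is an **ISE SNP** when
either allele has at least one hit — the per-allele hit sets also classify the
variant's effect as motif *loss* (reference-only hits), *gain* (alternate-only),
or *retention/shift* (both alleles hit, possibly different motifs).

Scanning operates on pre-mRNA sense sequence: for SNPs hosted by minus-strand
genes the window is reverse-complemented after allele substitution (alleles are
declared on the plus strand, as in VCF). When no gene models are supplied the
scanner falls back to plus-strand-only scanning, which is also available
explicitly (`strand_mode="plus"`).

## Skipped-exon detection and linking

Exons are compared across all isoform pairs of a gene. An internal exon *E*
(exact-coordinate identity) is **skipped** when some isoform contains *E* as an
internal exon and another isoform of the same gene contains no exon with
identical coordinates. First and last exons of an isoform are never candidates
and never count as inclusion evidence — a terminal exon is by definition
neither "skipped" nor "included". The default rule is deliberately lenient; a
strict cassette mode additionally requires the excluding isoform to contain
both flanking exons of *E*, removing alternative-first/last-exon artifacts.
Exon identity across annotation sources is exact by default since fuzzy
reconciliation rules are not well determined; `merge_as_sources` pools
transcripts by gene id (optionally by span-overlap clustering) and collapses
duplicate isoforms.

An ISE SNP is linked to the nearest exon on each side of its host intron,
using the union of exon boundaries over all transcripts of the host gene (the
analysis ties SNPs to exons, not to particular isoforms). Host genes are
restricted to the SNP's reported strand. Distance is the number of bases
strictly between the SNP and the nearer exon boundary, so a SNP at the first
intronic base is at distance 0. A SNP with at least one link to a skipped exon
is an **exon-skipping ISE SNP**.

## Splicing Index

SI is the per-sample ratio of exon-level intensity to the gene-level intensity
of the host gene. SI = 1 means the exon is included in proportion to overall
gene expression; |1 − SI| is the exon-skipping phenotype. Although the source
statistic is sometimes described on a log scale, the operational thresholds
(SI > 1.2 or SI < 0.8, strict) and the |1−SI| phenotype centered at 1 are only
coherent on the ratio scale, so ratio is the default and `log2_ratio` is kept
behind a flag; the conflict is resolved here explicitly rather than silently.
Gene intensities below a floor (10⁻⁶ × the median gene intensity) give NaN SI,
excluded from calls and association. An exon is "frequently skipped" when
strictly more than `min_individuals` samples call it (18 for 176 samples —
the top-10% rule generalized by `top_fraction`).

Array exons are mapped onto model exons when the overlap exceeds 95% of the
array exon's length **and** 90% of the model exon's length; among multiple
candidates the pair maximizing the summed fractions is kept.

## Association

For each linked (SNP, skipped exon) pair, |1 − SI| is regressed on the counted
allele dosage (additive model, ordinary least squares); the two-sided p-value
comes from the slope's t statistic and R² is the squared Pearson correlation.
Missing data are dropped pairwise; pairs with fewer than 3 complete samples or
a monomorphic dosage are flagged untestable and excluded from the FDR batch.
The **skipping allele** is the allele whose dosage increases |1−SI| (the
counted allele iff the slope is positive). Reported hits satisfy p < 0.05,
q < 0.10 and R² > 0.03, all strict.

Multiple testing uses Storey q-values: raw π0(λ) = #{p > λ}/(m(1−λ)) on the
grid λ = 0.05…0.95 (step 0.05) is smoothed with a cubic polynomial fit and
evaluated at λ = 0.95, clipped to (0, 1]. For batches under 100 tests, or when
the fit degenerates, π0 falls back to 1, which makes the q-values identical to
Benjamini–Hochberg step-up adjusted p-values (verified against an independent
implementation in the tests).

Supporting statistics: the per-genotype group comparison is an unpaired
two-tailed t-test (Welch by default; pooled-variance optional), and pairwise
LD (r², D′) is estimated from unphased dosages by the standard two-locus EM
that resolves double-heterozygote phase iteratively. r² = D²/(pₐp_Ap_bp_B),
D′ = |D|/D_max.

## Matched-resampling enrichment

To ask whether a query SNP set (e.g. a trait catalog) is enriched for an
annotation (e.g. exon-skipping ISE SNPs), the background pool — intronic SNPs —
is partitioned into MAF bins of width 0.05 over [0, 0.5], optionally crossed
with 8 log10-spaced distance-to-nearest-exon bins (distances offset by +1 so
zero is representable). 1000 random sets are drawn, each reproducing the
query's per-bin histogram exactly, uniformly without replacement within a set.
The empirical p-value is (1 + #{null ≥ observed})/(N + 1): ties count against
enrichment and p is never exactly zero, consistent with reporting "p < 0.001"
when the observed count exceeds all 1000 nulls. Query SNPs may be drawn into
null sets by default; `exclude_query` removes them from the pool. Bin widths
and counts are declared configuration, not inferred: the matching procedure
specifies a "spectrum", not widths.

Distance-stratified enrichment restricts the annotation to exon-skipping ISE
SNPs strictly closer than each threshold (60, 200, 1000, 5000 bp) and runs one
test per stratum.

## Synthetic data

The generator emulates the statistical structure of the study's inputs without
any external resource. Genes (default 30 per run; 4–8 exons of 80–200 bp,
introns 300–1500 bp, ~30% on the minus strand) are laid out on one chromosome
of uniform-composition random sequence. About half of internal exons are drawn
as cassette exons, each realized by an isoform that omits exactly that exon.
With probability `plant_rate` (0.8) a cassette exon's adjacent intron receives
a planted SNP whose *reference* allele completes a motif from a random 64-mer
motif set and whose alternate allele matches nothing (a motif-loss variant);
the SNP's distance to the exon is log-uniform on [6, 400] bp. The 11-mer
context around a planted SNP is resampled until the reference window's only
hit is the planted motif and the alternate window is clean, so planted truth
is exactly recoverable; elsewhere the background sequence is left alone, and
background SNPs that coincidentally hit motifs are legitimate nulls.

Genotypes are Hardy–Weinberg: alt-allele dosage ~ Binomial(2, MAF) with MAF ~
Uniform(0.05, 0.5), independent across SNPs (a two-SNP generator with
specified haplotype correlation supports the LD tests). Gene intensities are
log-normal; for a planted cassette exon the skipping magnitude is

    |1 − SI| = beta_skip · dosage + |N(0, si_noise_sd)|,   SI = 1 − magnitude

floored at SI = 0.01. The half-normal noise acts on the skipping magnitude
itself, making the association phenotype exactly linear in dosage — with
symmetric noise folded through |1−SI| the regression slope would be biased
downward by ~20% at the default effect size (0.15 per allele copy, noise sd
0.05, 176 samples), which would contradict the generator's contract that the
planted effect is recoverable without bias. Constitutive exons get symmetric
Gaussian wobble around SI = 1. The trait catalog admits each SNP with base
probability 0.05, multiplied through an odds factor (default 5) for planted
exon-skipping ISE SNPs; odds = 1 yields a fully null catalog used for
calibration.

What the generator does **not** model: realistic site-frequency spectra,
recombination and population structure (CEU/YRI differences), LD between
planted SNPs, array probe effects, and motif co-occurrence or clustering.
Passing tests therefore demonstrate correctness of the inference machinery
under its own assumptions, not performance on real cohorts.

## Verification strategy and problem sizes

Every algorithmic core is checked against an independent oracle: motif
matching against a brute-force 6-wide slide over 10,000 random windows;
skipped-exon detection against brute-force all-isoform-pairs comparison on
1,000 random gene models; q-values against an external Benjamini–Hochberg
implementation at π0 = 1; EM-based LD against simulated haplotypes with known
r². Statistical behavior is checked by calibration: null enrichment p-values
over 500 replicates (200 draws each) are tested one-sidedly against
Uniform(0,1) — super-uniformity from the +1/(N+1) estimator is allowed,
anti-conservatism is not; the association stage at zero effect keeps the mean
false-discovery proportion within the FDR target over 200 replicates; and the
planted effect (0.15, noise 0.05, 176 samples) is recovered with mean within
2 SE over ~700 planted SNPs pooled from three replicate cohorts, with power
above 0.8 at the reporting filter. These replicate counts and cohort sizes
were chosen to keep the full suite under a minute of simulation time while
leaving Monte-Carlo error well below each test's margin.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open everywhere inside the package; GTF and VCF
  conventions are converted at the I/O boundary only, and `chr` prefixes are
  stripped.
- MAF is stored folded; an input frequency > 0.5 is an error rather than being
  folded silently.
- Multi-allelic and indel records are dropped (the hexamer scan presumes a
  single-base substitution), with the count logged.
- A genome base disagreeing with the declared reference allele logs a warning
  and both declared alleles are substituted into the observed context.
- Skip-call and filter inequalities are strict exactly as stated (SI = 0.8 is
  not a call; p = 0.05, R² = 0.03, q = 0.10 are not hits).
- Degenerate statistics are flagged, not guessed: monomorphic SNPs are
  untestable in association and undefined in LD; single-value groups report no
  SD; t-tests require n ≥ 2 per group and some variance.

## Known limitations

- Exact hexamer matching only; no position-weight matrices or degenerate
  motifs, and no ESE/ESS/ISS resources are bundled.
- Exon-skipping detection ignores alternative 5′/3′ splice sites, intron
  retention and mutually exclusive exons.
- The enrichment test is SNP-level; no LD-aware clumping of the query set.
- cis-eQTL status is consumed as an annotation (4 Mb window, p < 0.01 labels);
  eQTL discovery itself is out of scope, as are array preprocessing and
  protein-structure consequences of skipping.
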