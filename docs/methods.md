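# Methods

This note documents the models behind each `invrad` component, the tunable
parameters and their defaults, what the synthetic-data generators do and do
not emulate, and the numerical choices made where the design was open.

## Data model

SNP data live in a `GenotypeDataset`: per chromosome, a samples × variants
matrix of ALT-allele dosages in {0, 1, 2, missing}, with 1-based strictly
increasing positions (BED export converts to 0-based half-open). Only
biallelic SNPs are retained at VCF import; multi-allelic records and indels
are dropped and counted. Missing genotypes are excluded pairwise from every
downstream statistic — nothing is imputed, because any imputation model
would leak assumptions into statistics whose whole point is to detect
departures from genome-wide structure.

Ancestral alleles are assigned by outgroup genotype agreement: the allele
whose frequency among non-missing outgroup haplotypes reaches
`min_outgroup_agreement` (default 1.0) is called ancestral; otherwise the
SNP stays unpolarized and is skipped by polarization-dependent statistics.
This is a deliberate simplification of probabilistic alignment-based
ancestral inference: it is exact when outgroups are fixed, and it
mispolarizes the (identifiable) minority of sites where the outgroup lineage
itself carries the derived allele. Polarization is idempotent and derived
dosage is `2 − ALT dosage` wherever the ancestral allele is ALT.

## Region detection

Within each window (default 1 Mbp, step = size/2; the test suites and the
bundled smoke scenario use 200 kbp windows matched to their chromosome
sizes), the pairwise distance between samples i and j is the mean over
pairwise-complete sites of |dᵢ − dⱼ|/2 — a proper semimetric in [0, 1] on
complete data. Classical multidimensional scaling (eigendecomposition of the
double-centered squared-distance matrix) gives per-window principal
coordinates; non-positive eigenvalues contribute zero coordinates. Windows
with fewer than 25 SNPs or more than 50% missingness are skipped.

Each window's feature vector is the concatenation of its first two PCs,
sign-aligned to a genome-wide anchor profile (a PC is negated when its
correlation with the anchor PC is negative; zero-variance or exactly
orthogonal PCs are left alone) and standardized within the window. Outlier
regions are found by *iterative* k-means: the current background windows are
split with k = 2 (10 restarts, fixed seed); the majority cluster stays
background, the minority becomes an outlier class, and the split is repeated
on the remaining background. Iteration matters because distinct inversions
carry independent karyotype compositions — their windows form distinct
clusters, and a single k = 2 split can absorb whole regions into the
background. Each stage must achieve a mean silhouette of at least 0.4,
otherwise the iteration stops: k-means always produces k clusters, and
without a separation criterion chance runs of noise windows on a null genome
would be called. The threshold sits between the silhouette of genuinely
clustered window sets (≈ 0.8–1.0 in planted data) and of arbitrary splits of
homogeneous window sets (≲ 0.2). Maximal runs of ≥ `min_run` (default 3)
consecutive outlier windows become region calls; runs separated by fewer
than `min_run` background windows are merged. The method assumes the genome
background has a *consistent* relationship structure (clades, population
structure) against which inversion regions stand out; on data with no
background structure at all the anchor alignment carries no information.

## Inversion genotyping

Within a called region: PCA of the mean-imputed, centered dosage matrix is
fitted on a reference panel (default: all non-outgroup samples) and every
sample is projected onto PC1. One-dimensional k-means with k chosen from
{2, 3} — the larger relative within-dispersion improvement
(W₍ₖ₋₁₎ − Wₖ)/W₍ₖ₋₁₎ decides — recovers the karyotype clusters. With k = 3
the middle cluster is heterozygous and the end cluster nearest the outgroup
projection is genotype 0 (homozygous ancestral); with k = 2 (one homozygote
class absent) the higher-heterozygosity cluster is heterozygous and the
other cluster's genotype follows outgroup polarity. If the middle cluster is
not the most heterozygous the call is flagged invalid. Assignment confidence
is 1 − d₁/d₂ (distance to nearest vs second-nearest centre); samples below
0.2 are left unassigned — this guards against intermediate projections of
lineages that are related to, but not members of, either haplotype class.
Without outgroups, genotypes are reported up to a 0↔2 label swap.

Region heterozygosity is reported as heterozygous SNPs per 10 kbp of region
length. In every planted scenario the heterokaryotype mean exceeds both
homokaryotype classes; this ordering is validated, not assumed.

## Rephasing and carrier haplotypes

Rephasing assigns each sample two allele vectors with orientation-class
labels. Homokaryotypes contribute two copies of their class (a heterozygous
site in a homokaryotype is class-resolved even though the copies cannot be
ordered — this is what makes within-class polymorphism observable).
For heterokaryotypes, at each heterozygous site the allele matching the
inverted-class consensus (majority allele over genotype-2 samples, by allele
counting) goes to the inverted copy; consensus ties leave the site
unassigned. When one homozygote class is absent (the configuration where an
orientation exists only in heterozygotes), its consensus is derived by
subtracting the known class consensus from heterozygote dosages — the same
rule used by `extract_carrier_haplotype`, which additionally reports per-site
support as the fraction of heterozygous carriers consistent with the call.

## Selection statistics

Inversion-correlated SNPs (ICS): Pearson correlation r between derived
dosage and inversion genotype over samples complete in both, with p from the
t distribution on n − 2 df and score = −log₁₀ p capped at 300. Monomorphic
SNPs and SNPs with < 10 complete observations are skipped. A seeded
permutation p-value is available for small n, where the t approximation is
visibly coarse. Sign convention: r > 0 means the derived allele rides on
inverted haplotypes; re-polarizing a SNP negates r exactly. The default ICS
threshold is score ≥ 7 and |r| ≥ 0.9; both are configurable and reported
with the output, and analyses of cohorts much smaller than ~1,000 haplotypes
should relax |r| (at |r| ≥ 0.9 a 100-haplotype cohort admits at most a copy
or two of discordance, which all but excludes shared polymorphism by
construction).

Exonic enrichment is a 2×2 Fisher exact contrast of (ICS vs non-ICS) ×
(exonic vs non-exonic), where exonic means synonymous or nonsynonymous.

McDonald–Kreitman counts classify each coding site once: a fixed difference
if the two orientation classes are fixed for different alleles, polymorphic
if either class is variable. NI = (Pn/Ps)/(Dn/Ds), DoS = Dn/(Dn+Ds) −
Pn/(Pn+Ps); zero denominators flag the statistic undefined rather than
raising.

Binned dN/dS: coding SNPs are binned by r (width 0.1, partitioning [−1, 1],
top bin closed at 1) and each bin's ratio is (n_nonsyn/L_n)/(n_syn/L_s)
with global Nei–Gojobori site counts — per codon, each position contributes
the fraction of its three single-base changes that are nonsynonymous;
changes creating stop codons are excluded from both numerator and site
counts, and stop codons are skipped. Under strict neutrality this
normalisation forces every bin toward 1; values above 1 require positive
selection, which is exactly what makes the top-positive-bin value the
decisive statistic.

Shared polymorphism: the fraction of ICS at which both alleles occur on at
least one haplotype of each orientation class, computed from the rephased
class haplotypes.

## Introgression and divergence

Divergence time: d is the mean per-bp difference over the scope (differences
summed over SNPs, divided by scope length in bp — invariant sites count as
zero), and t = d/(2μ) with μ = 3×10⁻⁹ per bp per generation by default. The
bp normalisation (not per-SNP) is what makes t a coalescence time; the
per-SNP distance used in window profiles serves a different purpose. Scopes
below 1,000 bp (configurable) are rejected.

Patterson's D: per SNP, ABBA = (1−p₁)p₂p₃(1−p_O) and BABA = p₁(1−p₂)p₃(1−p_O)
on complete-case population allele frequencies; D = (ΣABBA − ΣBABA)/(ΣABBA +
ΣBABA) with SE from a delete-one jackknife over contiguous blocks (default
1 Mbp; fewer than 20 non-empty blocks is an error because the jackknife is
then unreliable). D is exactly antisymmetric under swapping P1 and P2.

The conditioned-D experiment computes D outside all called inversion regions
for quartets in which exactly one of P1/P2 shares the focal inversion state
with P3, ordered so P2 is the sharing species. Under a null in which
inversion states are assigned independently of gene flow, the per-quartet D
values are symmetric around zero (summarised by a two-sided sign test);
inversion transfer accompanied by genome-wide admixture shifts them
positive. Holm correction is provided for families of quartets.

ILS retention: the probability that a neutral polymorphism survives t
generations of independent sorting is approximated by the heterozygosity-
decay factor exp(−t/(2Nₑ)), raised to (lineages × inversions) for joint
retention. This factor equals the expected fraction of heterozygosity
retained, (1 − 1/(2Nₑ))ᵗ, to O(1/Nₑ); it *understates* the probability that
a locus is merely still segregating (for p₀ = 0.5 at t = 2Nₑ that
probability is ≈ 6p₀q₀e⁻¹ ≈ 0.55 by the diffusion eigenexpansion). The
companion forward Wright–Fisher oracle therefore measures mean relative
heterozygosity retained, the quantity the formula approximates.

## Association tests

Heterozygote excess uses Levene's exact conditional distribution of the
heterozygote count given the allele counts, one-sided toward excess
(P(n_het ≥ observed)); monomorphic species return p = 1 with a flag.
Species are pooled with Fisher's method (−2Σln p ~ χ² on 2k df) over species
with at least one heterozygote; exact zeros must be floored explicitly by
the caller. Raw-count pooling of sex–genotype tables is provided as an
alternative. Genotype–sex association uses the two-sided Fisher exact test
(probability-mass definition), oriented so that an odds ratio above 1 means
male-heterozygote enrichment — the XY-like expectation in which an
ancestral-orientation haplotype acts as a Y. Exact conditional tests are
conservative in small tables: at nominal α = 0.05 the realised type-I rate
is ≈ 2% at 40 samples and reaches the nominal level only around 100 samples.
The default 2×2 collapse (het vs hom) keeps every sample; a het vs
homozygous-inverted collapse that drops genotype-0 samples is available.
Mendelian segregation is the χ² test against 1:2:1 with 2 df, for which the
p-value is exactly exp(−χ²/2).

## Synthetic data

`simulate_radiation` builds the neutral genome backbone with msprime
(binary mutation model, so every variant is a biallelic SNP): clades split
on a user-specified tree with per-population Nₑ, pulse admixture implemented
as mass migration, mutation rate 3×10⁻⁹/bp/generation and recombination
10⁻⁸/bp by default. Inside each inversion region the backbone is replaced by
a dedicated coalescent in which the two orientation classes are populations
that split at the inversion origin and never recombine with each other —
heterokaryotypes are genuinely two divergent haplotypes, and recombination
suppression holds by construction. Each orientation class defaults to half
the mean clade Nₑ. An optional symmetric "gene-flux" migration rate between
classes (default 0) mimics rare double crossovers and gene conversion.
Clades declared as outgroups draw their region haplotypes from a lineage
that splits *from the ancestral-orientation class* at the clade's own split
time (clamped below the inversion origin): the modelled inversions are old,
trans-radiation polymorphisms, which is what makes the outgroup genuinely
closer to the non-inverted class and outgroup-based orientation polarity
meaningful. A side effect faithfully reproduced from real data: mutations
fixed on the ancestral-class branch before the outgroup split are shared
with the outgroup and hence mispolarized by outgroup agreement. Karyotype
truth is drawn per sample from clade-wise inverted-haplotype frequencies
(Hardy–Weinberg), or forced by sex under XY-like linkage (males
heterozygous, females homozygous inverted). Per-SNP effect classes are
annotated at random (defaults 90% noncoding / 3.5% synonymous / 6.5%
nonsynonymous — enriched relative to real genomes so that coding statistics
are testable at simulation scale). What the generator does *not* emulate:
within-class clade structure inside inversion regions, sequencing error and
missingness, linked selection, and inversion breakpoint effects — passing
tests demonstrate correct recovery of planted population-genetic structure,
not robustness to artefacts of real callsets.

`simulate_cross` is a marker-grid pedigree: homozygous founders of opposite
orientation, two F1s, then F2 (F1×F1) and F3 (random F2 pairs). Gametes of
region-heterozygous parents carry zero crossovers inside the suppressed
region and Poisson crossovers elsewhere at the configured Morgans/bp;
homokaryotypic parents recombine freely (their in-region crossovers join
identical-by-class haplotypes and are invisible in genotypes, as in real
crosses). True crossover positions are recorded per gamete.

`simulate_selection_forward` is a discrete-generation Wright–Fisher model of
coding variation on two non-recombining inversion backgrounds held at
constant census frequency (a balanced polymorphism). Mutations arise as a
Poisson stream per background (rate Nᵦ·u·L with u = 2.5×10⁻⁷ per site per
haplotype per generation over 100 genes × 300 codons plus 100 kbp of neutral
noncoding sequence) and evolve as independent binomial trajectories within
their background — free recombination inside a background, none between.
Nonsynonymous mutations arising on the inverted background are beneficial
with probability `f_beneficial` (coefficient `s_beneficial`), otherwise
deleterious (`s_deleterious`); synonymous and noncoding mutations are
neutral. The mutation rate was chosen so that a 4Nₑ-generation run at
Nₑ = 1,000 accumulates tens of synonymous substitutions per background,
enough to resolve binned dN/dS. Cohorts for correlation analyses are drawn
from the final within-background frequencies under Hardy–Weinberg karyotype
sampling.

## Problem sizes used by the test and acceptance suites

Simulated scenarios are sized to give each statistic adequate power at
laptop scale: detection/genotyping scenarios use 60 samples and 8 Mbp
chromosomes with 3 Mbp inversions (origin 60,000 generations, Nₑ = 5,000);
D-statistic calibration uses 40 null and 5 introgression replicates of a
10 Mbp four-population quartet at Nₑ = 10,000 (the planted 10% pulse is
summarised by the median Z over replicates because a pulse into ~16 sampled
lineages has large realization variance); divergence-time recovery uses a
10 Mbp two-population split. The pipeline smoke scenario completes in a few
seconds; the whole suite runs in minutes on one CPU.

## Known limitations

- Orientation polarity requires either outgroup samples or external
  knowledge; without them genotypes are defined up to label swap.
- The ICS default threshold targets large cohorts; small cohorts need a
  relaxed |r| cutoff (see above).
- The ILS formula is a heterozygosity-decay approximation, not a segregation
  probability (see above).
- The forward simulator's free-recombination-within-background assumption
  means it cannot produce linked-sweep signatures; it is designed to test
  the binned dN/dS contrast, not haplotype structure.
- Breakpoint-resolution refinement, variant calling, annotation computation
  and statistical phasing outside inversion regions are out of scope.
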