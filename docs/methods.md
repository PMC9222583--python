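# Methods

This package re-implements, as a tested pipeline over synthetic data, the
quantitative core of an ecomorph-divergence analysis on pooled
transcriptomes: pool-seq SNP and F_st statistics with an
alternatively-fixed-SNP criterion, tiered negative-binomial differential
expression, tissue-wise divergence comparisons, candidate-gene filters, and
landmark morphometrics. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic data do and do not
emulate.

## Population divergence from pooled allele counts

**Coverage standardization.** Expression variance distorts pooled SNP
detection, so every site is brought to a uniform target depth (default
20x) per pool by sampling reads without replacement — a multivariate
hypergeometric draw over the pool's four nucleotide counts. Sites where
any pool is below the target are removed entirely. N and deletion counts
are excluded from coverage and from allele calling. Subsampling RNG
streams are derived per (contig, position, pool) from one seed, so results
do not depend on site order.

**SNP calling.** Alleles are ranked by summed count over all pools;
third-ranked and lower alleles' reads are discarded (ties between the 2nd
and 3rd allele break deterministically by A < C < G < T). A site is kept
as a biallelic SNP iff the minor-allele frequency over the combined pools
is at least the threshold (default 10%, boundary kept). The MAF filter is
global (one SNP list over all pools), not per-comparison.

**F_st estimator.** The SNP-wise estimator is the classical heterozygosity
form. For two comparison units with major-allele frequencies p_1, p_2:

    pi_u      = 1 - p_u^2 - q_u^2          (= 2 p_u q_u)
    pi_within = (pi_1 + pi_2) / 2
    p_bar     = (p_1 + p_2) / 2
    pi_total  = 2 p_bar q_bar
    F_st      = (pi_total - pi_within) / pi_total,   0 when pi_total = 0

No finite-coverage bias correction is applied. This is a deliberate
estimator assumption: the uncorrected form hits both endpoints exactly
(F_st = 0 for identical units, F_st = 1 for units fixed for different
alleles), which the alternatively-fixed-SNP criterion requires;
bias-corrected variants do not. Defining F_st = 0 at pi_total = 0 makes
within-morph comparisons at fixed sites read 0, so the af-SNP criterion is
evaluable. Sliding windows and variance-component (Weir–Cockerham-style)
estimators are out of scope.

**Median pairwise matrix and combined distribution.** The pool-by-pool
matrix holds the median SNP-wise F_st per pool pair (diagonal 0; pairs
with no shared SNPs flagged missing). The between-ecomorph distribution
sums each morph's pools per site (three 20x pools giving a 60x unit per
morph), re-applies the MAF filter on combined counts, and reports the full
distribution with its median and mean.

**af-SNP detector.** A SNP is alternatively fixed iff every pool is
monomorphic and the two morphs are fixed for different alleles. This is
equivalent to F_st = 0 for every within-morph pool pair and F_st = 1 for
every across-morph pair; the equivalence is asserted as a tested
invariant. The percentile at which the af-SNP class starts within the
combined F_st distribution is reported as a descriptive statistic only —
it is never used as a selection device.

## ORFs and codon effects

The ORF finder scans the forward strand only (the emulated libraries are
strand-specific) for complete ATG...stop spans, length a multiple of 3 and
at least 30 nt (configurable; the floor guards against spurious micro-ORFs
in random flanks). The longest span wins, leftmost on ties; candidates
containing N are skipped; transcripts without a complete ORF are excluded
and counted. Partial (stopless) ORFs are deliberately ignored — the
classifier needs complete codon frames.

A SNP inside the ORF is classified by building its codon twice — once with
the major, once with the minor allele, the other two positions taken from
the transcript — and comparing translations under the standard genetic
code (hardcoded in the package; tests cross-check all 576 single-base
codon substitutions against an independent translation library). Major
vs minor (rather than reference vs alternative) is compared because a
pooled assembly reference may carry either allele. Positions outside the
ORF are noncoding; codons containing N are not-applicable.

Per-gene non-synonymous af-SNP density is the count per kb of ORF, with
folds against (a) the mean density over all ORF-bearing transcripts and
(b) the mean over transcripts carrying at least one af-SNP.

## Differential expression

The DE caller is self-contained rather than a wrapper around an external
tool; its three stages are:

1. **Library sizes** by median-of-ratios: size factor per sample = median
   over genes positive in every sample of count / per-gene geometric
   mean, rescaled to count units by the geometric-mean total. Below 50
   such genes it falls back to raw totals.
2. **Common dispersion** by trimmed method of moments on counts normalized
   to the common scale: within each (morph, tissue) replicate group,
   phi_g = max(0, (s^2 - m) / m^2); the per-gene estimates are averaged
   over groups first and then summarized by a 20%-per-tail trimmed mean
   over genes with normalized mean >= 5. Averaging within-group estimates
   before trimming matters at n = 3: the single-group estimate is so
   right-skewed that a trimmed mean of it underestimates a true phi = 0.2
   by more than 30%, while the group-averaged variant stays within about
   15%.
3. **Conditional exact test** per gene and tissue: counts are rescaled to
   the common library size and rounded; conditional on the grand total T,
   the first group's sum is compared against every split s + (T - s),
   with group sums distributed NB(n mu, phi / n) under the null (the sum
   of n iid NB(mu, phi) variables). The two-sided p doubles the smaller
   tail (splits as or more extreme than observed) and is capped at 1.
   Dispersion below 1e-8 switches to the exact Poisson conditional, a
   Binomial(T, n1/(n1+n2)) split. log2 fold change (rock vs wood) uses
   normalized group means with a 0.5 pseudo-count — the pseudo-count
   affects only the reported FC, never the test.

P-values are BH-adjusted within each tissue contrast separately (three
families, matching per-contrast DE calling). Tiers: DE requires FDR <=
1e-2 and linear |FC| >= 4 (|log2FC| >= 2); highly DE additionally FDR <=
1e-10. The FC gate applies regardless of FDR, so highly DE is a subset of
DE by construction. The FC threshold is interpreted symmetrically (fold
up or down). Tagwise/trended dispersion shrinkage, GLM designs and batch
correction are out of scope.

**FPKM.** count / (gene length in kb x effective library size in
millions). A gene is "expressed" in a (tissue, morph) when its mean FPKM
over that group's pools is >= 1; "expressed in a tissue" means expressed
there in at least one morph, while the SNP-based candidate filter demands
the flag in each morph separately. Mean-over-pools was chosen as the
least-noisy deterministic aggregation; the alternative (every pool >= 1)
only tightens the gate.

**Diagnostics.** The mapping-bias check is a two-sided Fisher exact test
on the 2x2 af-SNP-bearing x DE table over the common gene universe
(degenerate margins give p = 1 with a warning). The allele-collapse check
locally aligns every oppositely regulated pair of highly DE genes per
tissue (match +1, mismatch -1, gap -2, with an 11-mer prefilter) and flags
pairs with identity > 95% over at least 50% of the shorter sequence.

## Tissue-wise divergence

Genes (highly) DE in all three tissues are excluded from tissue-specific
proportions; genes expressed in all three tissues are excluded from af-SNP
frequency denominators. Per tissue, the DE and highly-DE proportions use
as denominator the genes expressed in that tissue (either morph) minus the
corresponding universal set. af-SNP frequency is the fraction of
denominator genes carrying at least one af-SNP, also restricted to af-SNPs
inside ORFs and to non-synonymous ones. All pairwise tissue contrasts use
two-sided Fisher exact tests (sidedness was an open choice; two-sided is
the conservative default), and percent-differences use the non-radula
tissue as baseline. Top-quantile composition pools all gene x tissue
tests (not genes), ranks by p ascending with ties broken by |log2FC|
descending then gene id, and reports each tissue's share of the top 1% and
5% (floor cut; shares sum to 1). The expression-distance trees and
correlation heatmaps are descriptive visualization and are not part of the
tested surface.

## Candidate genes

Expression-based candidates: radula FDR <= 1e-10 and |FC| >= 4, and for
each of mantle and foot FDR >= 1e-5 **and** |FC| <= 4 — the "not DE" gate
is implemented as the conjunction, reading the two conditions as joint
requirements; since the source phrasing is ambiguous the choice is flagged
here. A gene untested in a tissue fails the radula criterion and passes
the not-DE gate, with a logged count. SNP-based candidates: at least one
non-synonymous af-SNP and radula expression (mean FPKM >= 1) in both
morphs. The two sets are reported with their intersection; non-overlap is
an empirical observation, not a constraint, so nothing is forcibly
removed. The report includes the distribution of non-synonymous af-SNP
counts per SNP-based candidate (fraction with exactly one; maximum) and
the density-fold ranking.

## Morphometrics

**GPA.** Iteratively: center each configuration, scale to unit centroid
size, rotate to the current mean by 2-D orthogonal Procrustes (optimal
rotation from the SVD of the cross-covariance, determinant forced +1 — no
reflections), update the mean, renormalize it to unit size, and anchor its
orientation to the previous mean (without the anchoring the mean can
rotate indefinitely on high-variance data). Convergence when the mean
moves less than 1e-8 (default) or after 100 iterations. Realistic
landmark data converge in a handful of iterations; pure-noise stress
configurations converge only linearly and may need thousands.
Semi-landmarks are treated as fixed landmarks — no sliding criterion is
implemented; this is a known limitation.

**Shape PCA** is an SVD of the centered, flattened Procrustes residuals;
numerically null axes (singular value below 1e-12 of the largest) are
dropped, variance fractions sum to 1, and scores x loadings reconstructs
the residuals. Each PC with variance fraction >= 5% is tested between
ecomorphs with a Welch (unequal-variance) two-tailed t-test; PCs below the
gate are reported untested. Welch was chosen because the group variances
are not constrained equal. Radula ratio meristics are standardized to
unit variance before PCA (mixed units), constant variables dropped with a
warning. The habitat abundance test is a Pearson chi-squared on the 2x2
substrate x morph table, df = 1, without continuity correction.

## The synthetic-data generator

The generator emulates the emulated study's design — 2 ecomorphs x 3
tissues x 3 pools per morph, 19 + 18 landmark specimens — with fully
labeled truth for every stage. Key defaults (all in `SimConfig`):

| parameter | default | meaning |
|---|---|---|
| `mean_coverage` | 30 | Poisson site depth per pool; exercises the <20x removal path |
| `snp_rate_per_kb` | 10 | expected SNPs per kb of transcript |
| `af_snp_fraction` | 0.01 | fraction of SNPs planted alternatively fixed (~1% of SNPs) |
| `shared_maf_beta` | (2, 2) | Beta law of the common allele frequency at shared sites |
| `morph_fst` | 0.14 | Balding–Nichols divergence of morph frequencies around the common one |
| `nb_dispersion` | 0.1 | NB dispersion of expression counts |
| `planted_log2fc` | 3 | 8-fold planted expression changes |
| `de_fraction_per_tissue` | 0.05 | genes planted DE per tissue (scalar or per-tissue map) |
| `universal_de_fraction` | 0.01 | genes planted DE in all tissues |
| `orf_fraction` | 0.6 | fraction of each transcript covered by its planted ORF |
| `tissue_restricted_fraction` | 0.5 | genes silenced in a random proper subset of tissues |
| `shape_effect` / `shape_noise_sd` | 0.08 / 0.02 | radial mean-shape displacement on a third of landmarks; per-landmark noise |

Transcripts carry exactly one planted complete ORF each; a candidate is
regenerated whenever a stray complete ORF as long as the planted one
appears by chance, so the longest-ORF truth is unambiguous (multi-ORF
behaviour is tested on concatenated fixtures instead). At shared SNP
sites one common frequency per site is drawn from the Beta law and each
morph's frequency is then drawn around it by a Balding–Nichols
Beta(p(1-F)/F, q(1-F)/F) with F = `morph_fst`; all pools of a morph share
that morph's frequency, so within-morph differentiation is pure binomial
sampling while across-morph differentiation combines the planted
divergence and the af-SNPs. Setting `morph_fst = 0` yields a
pure-shared-variation background whose combined F_st reflects sampling
only. Planted af-SNP sites fix all wood pools for one allele and all rock
pools for the other at full drawn depth. Monomorphic filler sites (one
per SNP) are included. Landmark nuisance transforms use rotation uniform
on [0, 2pi), log-scale uniform on [-1, 1], and Gaussian translation — any
choice works, since GPA must remove them.

What the generator does **not** emulate: read-level data (no FASTQ,
mapping error, or duplicate reads), sequencing error in allele counts,
individual-level sampling within a pool (the pool frequency is the
sampling unit, whereas real pools contain 4–5 individuals), batch
effects, isoform structure, and multi-ORF transcripts. Passing tests
therefore demonstrate correctness of the estimators and filters under the
stated sampling models, not robustness to alignment artifacts or library
effects in real data.

## Reproducibility and problem sizes

Every generator and the coverage subsampler consume named substreams of a
single seed, so all outputs are byte-identical under a fixed seed; the
pipeline manifest stores relative paths only and is byte-identical across
reruns. The bundled analyses and the acceptance script run at desk scale
(600–1,000 transcripts, ~20,000 allele-count sites, 3,000–5,000 genes per
DE simulation, 37 landmark specimens), which keeps every stage in seconds
to a few minutes on one CPU; the statistics themselves are size-agnostic.
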