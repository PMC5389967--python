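# Methods

## Data model and conventions

All variant tables are ordered collections of biallelic sites over one
sample set, sorted by (chromosome, position), with 1-based point positions
(an MEI locus is represented by its insertion breakpoint). Genotypes are
stored as alternate/insertion-allele dosages 0/1/2 per diploid; −1 marks a
missing call and survives only until filtering. For insertions, absence is
the ancestral state: the reference genome lacks the insertion, so the
insertion allele is treated as derived throughout. SNP spectra can instead
be folded about n/2 (minor-allele convention) when ancestral states are
unknown.

MEI VCFs are read in either the structural-variant dialect (INFO/SVLEN) or
the MELT-style dialect (INFO/MEINFO span); the writer emits both, plus
explicit FAMILY and CLADE keys, so round-trips are lossless.

## Filtering

SNP filtering is site-wise: a site is kept only if its QUAL passes, it is a
biallelic SNP, and — after masking genotypes below the depth and genotype-
quality thresholds — the fraction of called genotypes reaches the
`min_fraction_called` threshold. The default (1.0) tolerates no missing
genotypes, so one failing genotype fails the whole site. Defaults are
minDP 6, minGQ 20, minQ 20. Sites lacking depth/quality annotations are
rejected and logged rather than aborting. Thinning keeps every `step`-th
site genome-wide in sorted order (per-chromosome thinning is a caller-side
subset, not the default). MEI callsets are merged per family, dropping loci
with any missing genotype or failing quality flag; duplicate calls — records
of different families within 50 bp — are clustered by single-linkage
chaining and resolved to the longest element, ties to the lowest position.
Chaining is the conservative reading of "within 50 bp of each other";
window-to-seed alternatives would keep more records.

## Estimators

Per-locus mean pairwise difference is the hypergeometric identity
π = 2k(n−k)/(n(n−1)) — the probability two sampled chromosomes differ —
averaged over loci. This per-locus reading (values of order 0.1–0.4)
matches how the quantity is tabulated per marker group, rather than a
per-genome sum. Multi-locus Tajima's D uses the 1989 constants computed
from n; sites monomorphic within the focal population contribute to neither
S nor π. D is undefined (an error, not 0) at S = 0.

Weir–Cockerham F_ST is the full 1984 two-allele, two-population variance-
component estimator with observed heterozygote frequencies (so it does not
assume Hardy–Weinberg within samples). The headline figure is the
arithmetic mean of per-site estimates over sites where a+b+c ≠ 0, matching
the per-site output convention of the common VCF tools; the ratio-of-sums
(weighted) estimator is also reported. Negative per-site estimates are
retained by default (clamping is available but changes means systematically).

The sharing partition classifies each locus carrying a variant allele as a
fixed difference (frequency 1 vs 0), private to one population, or shared;
the four percentages sum to 100 by construction.

Wilcoxon tests delegate to scipy: the signed-rank test drops zero
differences before midranking (the classical exact-test convention), reports
V = sum of positive-difference ranks, and uses full enumeration for ≤ 25
non-zero pairs; the rank-sum test reports the first sample's rank sum with
midrank tie handling.

## Demographic model

Two derived populations split from a common ancestor `t_split` generations
ago (fixed at 1,340,000 — 1.34 My at one generation per year; generation
time is an explicit assumption surfaced in the model object, not a fitted
quantity). Each derived population undergoes one instantaneous size change
at `t_change_*`; sizes are numbers of diploid individuals (the
"diploid population size" reading of the published estimates; a haploid
reading would halve all sizes — this choice is encoded in one place,
`DemographicModel.to_msprime`). Migration is continuous: `m12` is the
forward-in-time fraction of population 2 (Gulf) replaced by migrants from
population 1 (Florida) per generation, which backwards in time moves
lineages from Gulf to Florida — the mapping is implemented once and
documented in the module docstring to avoid silent transposition of the
"Gulf from Florida" / "Florida from Gulf" labels.

Genealogies come from msprime's structured coalescent. Unlinked sites are
independent single-site genealogies (no recombination machinery). Two
mutation modes:

* `FIXED_SITES_ONE_MUTATION` — exactly one mutation per site, placed
  uniformly on total branch length. Every site is polymorphic in the pooled
  sample, matching the ascertainment of SNP/MEI panels. The class law of a
  site is E[L_k/L_tot] over genealogies, *not* θ/k.
* `THETA_POISSON` — Poisson(θ/2 × L_tot/2N) mutations per genealogy, the
  unconditioned infinite-sites regime, used for closed-form expectation
  checks (E[S] = θ·a1, spectrum ∝ θ/k).

## Composite-likelihood fitting

The observed joint SFS is treated as multinomial over entries polymorphic in
the pooled sample (both monomorphic corners excluded); expected entry
probabilities at candidate parameters are estimated by simulation. Instead
of sampling one mutation per simulated tree, every branch contributes its
share of that tree's total length to its (k1, k2) entry — the exact
conditional law of a uniformly placed mutation — which matches the
generative model with much lower Monte-Carlo variance per tree. Expected
probabilities of zero at occupied entries are floored at
1/(10 × n_simulated_trees) and counted on the result object.

The search runs on log-transformed parameters (sizes, times and rates are
positive and span decades): per replicate, cycles of proposal/selection
where each cycle simulates a fresh expectation at a linearly growing budget
shared across all candidates of that cycle (common random numbers make the
within-cycle comparison fair), proposals mix single-coordinate and joint
log-normal steps with a decaying scale, and the best final composite
likelihood across replicates wins. The published schedule (40 cycles,
50,000 → 250,000 simulations, 100 replicates) is available as a named
preset; the desk-scale default is 10 cycles, 2,000 → 10,000 simulations,
10 replicates.

Because the likelihood uses SFS *proportions* only, the model family has a
soft ridge: rescaling all sizes by c (with migration rescaled by 1/c)
changes the likelihood by little when migration is appreciable — the same
weak identifiability visible in the published interval estimates, where
several size parameters span a 5–20× range. Fixing the split time anchors
part of the scale; the remaining shallow directions are resolved by an
optional polish phase: Nelder–Mead in log-parameter space on a surrogate
with one frozen simulation seed, making the objective deterministic so
ridge slopes of a few dozen log-likelihood units become visible. Parameter-
recovery tests use a four-parameter reduced model (two current sizes, one
ancestral branch size, symmetric migration; split and deep ancestral size
fixed) that is well-conditioned in this sense; recovery within a factor of
2 per parameter from a 50,000-site synthetic SFS runs in ~2 minutes.

Confidence intervals are parametric-bootstrap percentiles: datasets of the
original SNP count simulated under the best model, refitted (warm-started
at the estimate with a short schedule), 2.5/97.5 percentiles per parameter
over successful refits; failures are counted, never hidden. The PCA fit
check simulates spectra with parameters drawn uniformly from the CI ranges,
runs a singular-value PCA on entry-proportion vectors, projects the
observed spectrum, and declares it inside the cloud when its squared
Mahalanobis distance on (PC1, PC2) is within the empirical 95th percentile
of the simulated points' own distances (an empirical elliptical region;
a convex hull at these sample sizes is noise-dominated).

## Neutrality testing

Per-family nulls simulate `n_sims` replicates of the family's observed
locus count, each with parameters drawn uniformly from the 95% CI ranges
(the distribution over the CI is not specified by the estimation procedure;
uniform is the least-informative choice and is recorded in provenance).
Empirical p-values use the add-one rule (r+1)/(N+1), which cannot return 0
from finite simulation. Default sidedness is the lower tail for both D
(purifying selection predicts negative D) and F_ST (young, rare insertions
differentiate less than neutral SNPs); two-sided is available. Simulations
where the statistic is undefined (a family with no sites segregating within
the focal population — possible at small locus counts) are dropped and
counted, with a warning above 1%. The SNP block bootstrap draws a
chromosome (weighted by SNP count), a window size uniform in 100–500, and a
contiguous SNP run, pooling per-population D values into a model-free
comparison distribution.

## Synthetic data

The generators' defaults are the study conditions: 7 + 6 diploids, the
fitted demographic model, and SNP-conditioned unlinked sites. Synthetic
SNP VCFs carry constant passing DP/GQ/QUAL so the standard filter keeps
everything; a "dirty" fraction can be requested to exercise the filters.

Selection enters only through frequency distortion, not through the
genealogy: candidate neutral sites are accepted with probability
proportional to w(q) = (1 − e^{−γ(1−q)}) / ((1−q)(1 − e^{−γ})), the ratio
of the Wright–Fisher genic-selection sojourn density to its neutral limit,
evaluated at the pooled sample frequency and normalized by its maximum over
attainable frequencies. γ = 0 accepts everything (the neutral coalescent
law is recovered exactly, same random stream); γ < 0 thins high-frequency
derived alleles monotonically in |γ|. This is adequate for testing
frequency-based statistics; it does not model selection's effect on branch
lengths, linked sites, or segregation distortion, so passing tests say
nothing about haplotype-based signals in real data.

Truncation-length models per clade (full-length point mass plus a truncated
tail): uniform tail for R4 and RTE1 (truncation anywhere along the
element), linearly decreasing tail for CR1 and L2 (truncation probability
decays with distance from the 3′ end, so short copies dominate), and a
bimodal model for L1 (early abort below 1 kb or essentially complete).
Full-length fractions default to the observed per-clade complete fractions
(RTE1 0.62, L1 0.43, R4 0.41, CR1 0.09, L2 0.07, RTEBovB 0.04). Complete
copies are drawn within [90%, 100%] of the family maximum and truncated
copies strictly below 90%, so the completeness classifier is exact on
synthetic data. Family maximum lengths default to per-clade consensus full
lengths (R4 3.8 kb, RTE1 3.9, RTEBovB 3.2, CR1 5.8, L2 6.3, L1 6.8 kb),
with the observed per-family maximum as fallback for unconfigured families.

Real MEI data differ from these generators in ways that matter for
interpretation: genotyping error and dosage uncertainty from split-read
evidence, reference bias, length-estimation error, clustering of insertions
in low-recombination regions, and non-equilibrium transposition dynamics
(bursts) are all absent. The neutrality machinery therefore demonstrates
calibration (type-I error ≈ α against the generating model) and power
against frequency distortion, not robustness to call-set artifacts.

## Numerical and testing choices

* Problem sizes in the test suite are chosen for desk-scale runs: 20,000
  simulated SNPs for the model-vs-statistics checks, 50,000 sites for the
  recovery experiment, 500 trials for calibration checks; the full suite
  runs in about 7 minutes on one CPU.
* Monte-Carlo assertions use empirical batched standard errors where the
  naive multinomial calibration would be wrong (mutations sharing a
  genealogy are correlated).
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; msprime seeds are derived 31-bit values.
  Identical configuration + seed reproduces every output byte-for-byte.
* Known printed-table inconsistencies are preserved rather than silently
  corrected: the Florida per-individual mean implied by the per-sample
  column (71,545/7 ≈ 10,221) differs from the printed 10,022, and the R4
  full-length/truncated locus counts (1,017/712) are swapped relative to
  the clade table's 712 full-length; the packaged fixtures transcribe the
  tables as printed and tests assert only quantities stable under both
  readings.

## Limitations

* The simulator has no recombination, no linked selection, and exactly two
  derived populations.
* Composite-likelihood CIs ignore linkage between SNPs (sites are treated
  as independent; the thinning step is the mitigation).
* The published genome-wide parameter estimates themselves are not
  reproducible here without the original resequencing data; what is
  validated is the machinery (encoding, estimators, calibration) plus the
  simulation-level reproduction of the SNP summary statistics under the
  published model.
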