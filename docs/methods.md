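# Methods

## Generative model for the synthetic cohort

The generator (`varbatch.simdata`) emulates a pooled case/control exome
study in which three sequencing centers map onto two capture kits
(C1 → kit A; C2, C3 → kit B), so kit is perfectly confounded with center and
cannot enter the association model as an independent covariate.

**Population.** Each variant gets an ancestral allele frequency `p` drawn
uniformly from a configurable range (default 0.05–0.5). Subpopulation
frequencies follow the Balding–Nichols model, Beta(p(1−F)/F, (1−p)(1−F)/F)
with divergence `F = F_ST` (default 0.01 across 3 subpopulations; F = 0
degenerates to identical frequencies). Samples are assigned to
subpopulations uniformly and genotypes are Hardy–Weinberg draws from their
subpopulation frequency.

**Phenotype.** Case status follows an additive logistic model over the
causal variants. The intercept is solved numerically (Brent's method on the
mean predicted risk) so the expected prevalence matches the configuration
(default 0.5); optional per-subpopulation intercept shifts create the
population-structure confounding used in the λ_GC analyses. Ages are drawn
with cases older than controls, so the optional age-adjusted model (M3)
loses signal by construction.

**Capture bias and reads.** Capture efficiency `c ∈ (0, 1]` is the relative
probability that an alternative-allele template is captured versus a
reference template. For a genotype `g` sequenced at efficiency `c` with base
error `ε`:

* per-read alt probability: `π(0) = ε`,
  `π(1) = (c/(1+c))(1−ε) + (1/(1+c))ε`, `π(2) = 1−ε`;
* depth: negative binomial with kit mean `d` (default 40×, dispersion 8),
  scaled by `(1+c)/2` for hets and by `c` for alt homozygotes (template
  loss also reduces coverage).

One parameter therefore reproduces both the depressed AAF and the allele
dropout that characterise a biased kit. Genotypes are re-called by
flat-prior maximum binomial likelihood over alt fractions `{ε, ½, 1−ε}` —
deliberately ignorant of `c`, which is how dropout arises — with
GQ = −10·log10(1 − posterior), capped at 99, and calls below a depth floor
(default 4 reads) set missing. The site-level VQSLOD-like score is drawn
positive unless the configuration injects failures; the pipeline only
thresholds this score and does not model recalibration itself.

**Default scale and calibration.** Defaults are chosen once to mirror the
motivating study design at roughly 40% scale: center sizes (1788, 1317, 895)
preserve the study's 4427:3260:2217 ratio; 1,000 variants with 10 causal at
OR 4.0 and causal (control-side) MAFs 0.05–0.12, matching the effect sizes
implied by the study's printed case/control MAF table; 7 of the causal and
8 non-causal variants are capture-biased in kit B with `c = 0.01`, which
places the biased AAF mode near log2(AAF) ≈ −6 as reported for the biased
kit. Transitions make up 80% of sites: per-sample Ti/Tv over ~10³ synthetic
sites is far noisier than over a real exome's ~10⁵ sites, so the cohort mean
must clear the 2.75 QC floor by several per-sample standard deviations for
the floor to act as the outlier filter it is in practice.

## Quality control

Sample level (defaults as in large exome studies): SNP call rate > 0.95;
DP ≥ 10 at ≥ 90% of called variants; Ti/Tv > 2.75 among carried variants.
Variant level for association: biallelic SNP; VQSLOD > 0; exact
Hardy–Weinberg p ≥ 1e-6 in controls; ≥ 10 alt-supporting reads across the
cohort. Filters are evaluated independently so their application order
cannot change the retained set.

The HWE exact test conditions on allele counts and sums the probabilities of
all heterozygote counts no more probable than the observed one (two-sided
"probability ≤ observed" summation, not mid-p), computed with the standard
multiplicative recurrence; comparisons use a 1e-9 relative slack so
mathematically tied tables are classified stably. Monomorphic sites return
p = 1.

The PCA variant set additionally requires MAF ≥ 0.05 and all-sample HWE
p ≥ 1e-4 (the source study does not state which cohort its ancestry-pruning
HWE used; all samples is the common choice), drops configured
high-variability regions (none by default for synthetic genomes — the real
HLA/LCT/8p/17q coordinates are build-specific), and greedily prunes
left-to-right per chromosome, dropping the later variant of any pair with
mean-imputed dosage r² > 0.2 within 100 kb. Keeping the earlier variant on
ties makes pruning deterministic and position-stable.

A deliberate consequence worth knowing: strongly biased *common* variants
show a pooled-kit heterozygote deficit (a Wahlund-type effect of mixing one
kit's true frequency with the other kit's dropout-deflated one) and can be
removed by the control-HWE filter before association. This mirrors the
failure mode the diagnostics exist to surface — batch-discordant variants
being silently discarded — and is visible in the default run's exclusion
counts.

## Population structure

Dosages are mean-imputed per variant, centred by `2p̂`, and scaled by
`√(2p̂(1−p̂))` so each variant contributes unit variance under HWE; PCA of
unscaled dosages would overweight common variants. Eigenvalues are those of
the realised relationship matrix `XXᵀ/m`. Exact SVD is used for small
problems (≤ 4×10⁶ matrix entries), randomized truncated SVD with a fixed
seed above that; each component's sign is fixed by making its
largest-magnitude loading positive.

PC retention applies the eigenvalue-above-1 rule as printed in the source
study, but the pipeline computes only the top 10 components: when the
number of pruned variants is comparable to the sample count, bulk noise
eigenvalues of `XXᵀ/m` also exceed 1, and an uncapped rule would retain
hundreds of noise PCs. Ten covariates of near-noise PCs are harmless to
type-I error (verified by the null-calibration suite) while real structure
always sorts first.

Subpopulation labels come from k-means over retained PCs with k chosen by
maximum mean silhouette. This is a labelling surrogate — the source analysis
used model-based admixture estimation, but only for colouring and sanity
checks; covariates are always the PCs themselves.

## Association and batch-exclusive flagging

Each variant is fit by logistic IRLS (log-likelihood tolerance 1e-8, max 50
iterations) of case status on alt dosage plus covariates: M1 = center +
retained PCs; M2 = M1 + sex + major-locus genotype (coded as 0/1/2 dosage
of a designated variant); M3 = M2 + age. Center indicators drop out
automatically inside single-center strata. Samples missing the genotype are
excluded from that variant's fit. Wald p-values are the default (matching
the study's PLINK workflow); a likelihood-ratio option exists behind a
flag. Constant dosage yields a flagged NA; non-convergence or |β| > 10
(near-separation) is flagged, not rescued — no Firth correction is
implemented. Stratified analyses recompute PCs within the stratum by
default (global-PC reuse is a config flag); whether the source study did so
is unstated.

Significance uses the Bonferroni threshold α/#tests (α = 0.05). The
batch-exclusive flag formalises a visual notion: a full-cohort-significant
variant is `exclusive_<kit>` when that kit's stratum p is below the
per-stratum threshold (default: the same Bonferroni threshold) and the
other kit's p exceeds a null floor (default 0.05). A stratum in which the
variant was never called non-reference (constant dosage) counts as
maximal no-evidence — total dropout is precisely the phenomenon being
flagged. Both cut-offs are configuration, not statistics with coverage
guarantees; they are reported alongside the quantities they threshold.

λ_GC is the median Wald χ² over its null median (0.4549).

## Batch diagnostics

Per variant and kit: mean GQ and DP over samples with called genotypes;
mean AAF over samples selected by `aaf_mode` — default `carriers` (≥ 1
alt-supporting read, making "balanced ref/alt support" interpretable as
per-carrier allele balance), alternative `covered` (all samples with
DP > 0, the literal all-samples average). Ratios are log2(kit A / kit B),
defined only when both means are positive. Tail membership takes the
empirical 5% quantiles of each metric's ratio distribution with strict
comparisons (identical ratios give zero-width, empty tails); the
"any-metric" union feeds the subset-PCA analysis, mirroring tails "in GQ,
DP, or AAF".

Subset-PCA separation is the mean silhouette of kit labels on the first two
PCs of genotypes restricted to a variant subset — a quantitative stand-in
for visually "clear separation" in a 2-D eigenvector plot. AAF bimodality is
a two-component Gaussian mixture (EM, 20 restarts, fixed seed) on log2 mean
AAF; the flag requires both weights ≥ 0.05, mode separation > 2 pooled SDs,
and a BIC win over one component. MAF concordance folds to the minor allele
and compares absolute distances |MAF_kit − MAF_ref| (absolute rather than
log-fold, because biased-kit MAFs near zero would explode a ratio); the
winner-count sign test summarises which kit better matches the reference.
Capture efficiency is estimated as the per-variant mean of AAF/(1−AAF) over
het carriers (true hets when simulation truth is available, called hets
otherwise); carriers with AAF = 1 are excluded with a count. At depth ≳ 40
the estimator's Jensen bias is below ±0.02.

## What the synthetic data does and does not show

The generator reproduces the features the diagnostics rely on: kit-specific
AAF depression and dropout, center/kit confounding, subpopulation structure,
case/control effects, and depth/quality heterogeneity. It does not model
read alignment, indels, multi-allelic sites, relatedness, contamination,
linkage disequilibrium between variants (sites are drawn independently), or
sex chromosomes. Passing tests therefore demonstrate that the pipeline
detects and adjudicates *this* bias mechanism at desk scale; they do not
certify behaviour under LD-driven pruning pressure or alignment-induced
artefacts on real data.

Problem sizes in the test and acceptance suites are chosen for desk-scale
runs: null calibration uses 2,000 samples × 20,000 variants; planted-bias
adjudication uses the 4,000 × 1,000 default over five seeds; confounding
control uses 2,000 × 2,000 with F_ST = 0.05 and ±0.7 subpopulation logit
shifts.

## Numerical choices and degenerate inputs

All randomness flows from one integer seed through deterministically
spawned substreams, so reruns are byte-identical. Logistic fits clip the
linear predictor at ±30 and floor IRLS weights at 1e-10. PCA drops
zero-variance variants after imputation with a log entry. Silhouette-based
operations collapse to a single cluster for identical points. p-values of
exactly zero are nudged to the smallest positive float so p ∈ (0, 1]
holds. Tail partitions require ≥ 20 defined ratios; mixture fits require
≥ 50 finite values and drop non-finite inputs with a count.
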