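# Methods

This note records the models, conventions and numerical choices behind
`maburden`, in the order a user meets them.

## Data model and file handling

Genotypes live in a dense samples × variants `int8` array counting copies of
a per-variant *counted allele* (0/1/2; −1 missing), with pandas tables for
sample metadata (phenotype coded 0 control / 1 case / −9 missing) and
variant metadata (chromosome, 1-based bp position, SNP id, two alleles,
counted allele). Re-orienting the counted allele maps calls g → 2−g; doing
it twice is the identity, and every downstream statistic is either
invariant to orientation (MAC, r²) or transforms predictably (a logistic
coefficient flips sign).

PLINK text PED/MAP and TPED/TFAM are the interchange formats; text keeps
every fixture inspectable and diffable. These formats store *unordered*
allele pairs, so a freshly read matrix counts the first allele observed in
the file; `orient_like` restores a reference orientation, making
write → read → orient_like an exact identity. Binary BED is deliberately
out of scope.

When two cohorts genotyped on different platforms are intersected, shared
SNPs are matched by id; allele pairs must agree directly or after
complementing both alleles (a strand flip). Strand-ambiguous SNPs (A/T,
C/G) are dropped with a logged count — a flip cannot be detected for them
from labels alone, and frequency-matching them risks silent allele
swaps — and the second cohort's counted allele is re-oriented to the
first's. This harmonization policy is the module's own; alternatives
(frequency matching) exist but trade silent errors for yield.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not any
particular population:

- **MAF spectrum**: population minor-allele frequencies are drawn
  Beta(0.8, 2.2) rescaled to [0.01, 0.5] — right-skewed toward low
  frequencies, as genotyping arrays show, while bounded away from 0 so
  desk-scale cohorts stay polymorphic. Both shape and bounds are
  config-exposed.
- **Genotypes**: Hardy–Weinberg draws of two haploid layers given the
  frequency. Optional block-copula LD ties `ld_block_size` consecutive
  SNPs to one latent uniform per haplotype, with an independent per-SNP
  re-draw probability (`ld_flip_prob`, default 0.1); marginal frequencies
  are preserved exactly while within-block genotype r² becomes substantial.
  LD is off by default: most tests want exchangeable SNPs.
- **Disease model**: an individual's genetic score is
  Σ (copies/2) × effect over risk SNPs — the dosage scale matches the
  scoring rule in which a heterozygote contributes half a weight, so a
  generative effect of 0.4 corresponds to a per-allele-copy log-odds ratio
  of 0.2. The score is centred at its population mean before entering the
  logit, so `baseline_log_odds` (default −1, prevalence ≈ 0.27) sets the
  prevalence regardless of how many risk SNPs exist; without centring, a
  few hundred positive effects would push prevalence to 1 and make
  control sampling impossible.
- **Sampling**: case/control quotas are filled by rejection from a stream
  of population draws (batch ≥ 256), capped at `max_attempt_factor`
  (default 100) times the requested cohort size, after which a `QuotaError`
  names the shortfall. Rejection keeps control genotypes in exact HWE.
- **Missingness**: independent per-genotype masking at `missing_rate`
  (default 1%).
- **Cohort pairs**: a SNP universe of `n_a + n_b − round(overlap × n_a)`
  variants is drawn once; both cohorts' individuals are simulated over the
  whole universe (disease status reflects unobserved risk SNPs too, as in
  reality) and each cohort's delivered panel is a subset. Shared SNPs have
  identical frequencies and effects by construction.

What the generator does **not** emulate: population structure and
admixture, realistic recombination maps, genotyping error, batch effects,
sex chromosomes. Tests passing on these cohorts certify the statistical
machinery, not robustness to those artefacts.

## Quality control

Fixed order, recorded in the report: duplicates → PC outliers →
missingness/MAF → HWE. SNP-level filters depend only on genotype counts,
so they commute with sample reordering.

- **Exact HWE test**: the conditional test given allele counts, summing the
  probabilities of heterozygote counts no more probable than observed;
  probabilities come from the two-sided ratio recurrence started at the
  modal het count, which is stable at any sample size. Applied to controls
  only by default (cases may deviate at true risk loci); α = 0.01.
  A chi-square version was rejected because desk-scale fixtures routinely
  have cells < 5.
- **Missingness/MAF**: a SNP is removed iff missing fraction > 5% or
  control MAF < 1e-4, both strict, so boundary values survive.
- **Ancestry PCA**: the standardized GRM, (g − 2p)/√(2p(1−p)) averaged over
  pairwise-complete SNPs, eigendecomposed; samples more than
  `sd_multiplier` (default 6) SDs from the mean on any of PC1–3 are
  dropped in a single pass. The multiplier and the single-pass rule are
  package conventions — no standard exists — and are logged with the run.
- **Duplicates**: pairwise non-missing concordance on up to 10,000 SNPs;
  at ≥ 0.99 the later sample is dropped (deterministic order rule).

## Burden and association statistics

MAC uses the allele-count denominator 2 × called informative SNPs, making
it a proportion in [0, 1]; a per-SNP denominator would only rescale by 2
and group comparisons are scale-invariant, but the per-allele convention
keeps 1.0 meaning "homozygous minor everywhere". Missing genotypes leave
both numerator and denominator. Samples with zero called informative SNPs
get NaN, never 0. Group comparison is a plain one-way ANOVA on raw MAC
(for two groups F = t², cross-checked in tests); zero-variance equal-mean
degenerate input returns (0, 1) by convention.

Per-SNP weights come from maximum-likelihood logistic regression of case
status on minor-allele copies (0/1/2) with intercept and no covariates
(optional covariates are a deliberate non-feature of the default: the
upstream cohorts' sex imbalance is a documented caveat, not silently
adjusted away). Because the likelihood depends on data only through the
six genotype × phenotype counts, all SNPs are fitted at once by a Newton
iteration vectorized across SNPs (tolerance 1e-8 on the step, max 50
iterations). Wald p-values are two-sided normal. Fits with |log-odds| ≥ 15
are treated as separated; separated, non-converged and constant-genotype
SNPs are flagged and excluded from models rather than clamped. An
independent implementation (statsmodels) reproduces coefficients and
p-values to 1e-6 in the test suite, and the binary-genotype special case
equals the closed-form 2×2 log odds ratio.

The MAF-binned average risk partitions (0, ceiling] into equal-width bins
by control MAF and reports, per bin, the cohort-mean per-sample score
restricted to the bin divided by the bin's SNP count. Empty bins are
absent, not zero.

## Risk models and scoring

Selection: control MAF < ceiling (default 0.4), p < threshold (default
0.05), converged informative fits only, and by default the minor allele
must be more frequent in cases. Weights are the logistic coefficients.
Scoring: full weight for homozygous-minor, half for heterozygous, nothing
for missing (no mean-imputation), with the used-SNP count reported and a
per-used-SNP normalized column offered. When a model is reduced to a
shared panel no renormalization is applied — the raw sum remains the
score — matching the design in which a large panel reduction degrades but
does not invalidate the predictor. Thresholding is strict (score >
threshold), so a case tied with the best control is *not* detected;
setting the threshold to the maximum control score reproduces the
TPR-at-100%-specificity labelling exactly.

## Haplotype blocks

LD is measured as composite genotype r² (squared Pearson correlation of
copy counts, pairwise-complete), a deterministic, phase-free proxy for
haplotype r²; it is documented as an approximation to EM-phased estimates.
Blocks grow greedily left-to-right within each chromosome: a SNP joins the
current block iff it lies within 200 kb of the block's first SNP and has
r² ≥ 0.5 (config knob) with at least one member; otherwise a new block
starts. Blocks therefore partition the panel, singletons included, and
never span more than the window. Each block contributes at most one
representative — the member with the smallest association p among those
meeting the model criteria, ties broken to the smaller bp position. On
LD-free cohorts nearly every block is a singleton and the haplotype model
coincides with the plain SNP model under the same criteria, which the
tests assert.

## Evaluation

- **AUC**: rank-sum with ties half-credit; variance by DeLong's placement
  values (midrank formulation), normal 95% CI clipped to [0, 1]. Verified
  against R's `pROC::ci.auc` on a frozen example.
- **ROC**: one point per distinct threshold with ≥-classification; the
  trapezoid area equals the rank-sum AUC to 1e-12 (ties walk a diagonal),
  an identity the tests enforce on random tied data.
- **TPR at 100% specificity**: threshold = max control score, strict
  inequality, exact Clopper–Pearson 95% CI. Under exchangeability its null
  expectation is 1/(n_controls + 1), which calibration tests use.
- **External validation** trains entirely on the training cohort (minor
  alleles oriented from *training* controls), then reduces the model to
  the harmonized shared panel and scores the test cohort.
- **10-fold CV** stratifies folds by case status (plain random folds can
  lose a class at desk scale) and re-derives the MA set, weights and
  selection inside each training split; the held-out fold contributes
  nothing to any fitted quantity. Fold assignment is deterministic given
  the seed. Per-fold metrics are averaged.
- **Model sweep**: MAF ceilings {0.1, 0.2, 0.3, 0.4, 0.5} × p grid
  {1e-4, 1e-3, 0.01, 0.05, 0.1, 0.2, 0.5} plus a haplotype model at the
  0.4 ceiling; the sweep harmonizes panels first and computes one
  association table, reusing it across cells. Empty cells are recorded
  with NaN metrics, not zero.

## Problem sizes

The shipped analyses run at desk scale, chosen so the full suite and the
acceptance script each finish in minutes on one CPU while keeping every
statistical property measurable: 500 + 500 samples × 5000 SNPs for
workflow runs (50 risk SNPs at per-allele log-OR 0.2, 24% panel overlap
for cross-platform steps), 1000 + 1000 × 2000 for null calibration
(20 seeds), 100 + 100 × 5000 for the overfitting contrast, and a
polygenic burden setting of 1000 risk SNPs at per-allele log-OR ≈ 0.05
among 5000 for the MAC comparison. At these sizes the burden ANOVA is
decisively significant, recovery enrichment is astronomical when pooled
over seeds, and external AUC sits in the high 0.5s — weak by design, as
thinly spread polygenic signal through a reduced panel should be.

## Known limitations

Composite r² understates phased LD for rare alleles; the greedy block
rule is one of several defensible conventions (Gabriel confidence-interval
blocks would differ); no covariate adjustment, shrinkage or LD-aware
weighting is applied to the per-SNP models; the generator's independence
assumptions make QC's PCA outlier step vacuous on default fixtures (it is
exercised by targeted tests instead); and absolute score thresholds are
meaningful only on a fixed coefficient scale and SNP panel, so none is
hard-coded.
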