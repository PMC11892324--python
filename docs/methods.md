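# Methods

This note records the models, parameter choices and numerical decisions
behind `proxyrare`, and what the synthetic-data experiments do and do not
demonstrate about real biobank data.

## The problem and the strategy

MASLD phenotyping in EHR-linked biobanks is doubly censored: diagnosis
codes miss roughly 42–45% of true cases, and the quantitative imaging
phenotype (MRI proton density fat fraction, PDFF) is measured in under 10%
of participants. The strategy implemented here imputes log(PDFF) from
routine clinical features in the imaged subsample, applies the fitted
models to the whole cohort, and runs rare-variant association tests on the
imputed ("proxy") phenotype. A proxy with correlation r to the true trait
attenuates per-variant noncentrality by r², but is available on the full
cohort; whenever N_full·r² > N_imaging the proxy wins. With a 9% imaging
fraction and r ≈ 0.65 the expected gain is ≈ 0.09⁻¹·0.42 ≈ 4.7-fold in
noncentrality, and the acceptance suite measures the resulting power
ordering directly.

## Synthetic biobank

### Cohort and genotypes

Participants draw an ancestry label from (EUR 0.743, AFR 0.124, AMR 0.091,
SAS 0.022, EAS 0.016, MID 0.004). The EUR fraction matches the published
breakdown of the motivating study population exactly; the published
non-EUR fractions sum with EUR to only 94.9% (the remainder unassigned),
so the five non-EUR fractions are rescaled proportionally to fill the
complement. Ten principal components are ancestry-cluster means plus unit
noise; age, sex, alcohol intake and fasting time are independent
nuisance covariates.

Variants come in three frequency classes (common MAF ∈ [0.01, 0.5), rare
[10⁻⁴, 0.01), ultra-rare [10⁻⁵, 10⁻⁴)). Each variant has a shared base
frequency and per-ancestry frequencies correlated on the logit scale
(default correlation 0.8), clipped to the class range per ancestry; a
configurable number of ultra-rare variants are polymorphic only in AFR.
Genotypes are independent binomial(2, AF) draws within ancestry — exact
Hardy-Weinberg by construction, no linkage disequilibrium.

### Trait model

The latent trait is log-PDFF. A standard-normal metabolic factor M drives
a 20-feature panel (z_f = a_f·M + noise), and the latent trait is

    log PDFF = μ + s·Σ_f w_f z_f + (1 − u)·G + ε,   ε ~ N(0, σ²)

where G = Σ β_v·dosage_v (variant effects plus gene-level burden effects
through the gene's qualifying ultra-rare variants), u is the upstream
effect share (below), and s scales the feature signal to a fixed SD.
Defaults: μ = log 2.87, feature-signal SD 0.35, residual SD 0.727, so the
latent SD is ≈ 0.81 and the calibration yields a median PDFF of ≈ 2.9%
and steatosis (PDFF ≥ 5.5%) prevalence of ≈ 21%, the descriptive
statistics of the real imaging cohort. Planted effects are centered so
calibration does not drift with the effect configuration. Feature signs
follow the attribution structure seen in liver-fat predictors: BMI, waist
circumference, leg fat and triglycerides positive; SHBG and AST/ALT ratio
negative.

Two channels connect genotype to the feature panel, and both are essential
for the proxy mechanism to exist at all:

1. **Upstream routing** (u, default 0.6): a share of each planted effect
   acts through the metabolic factor (the adiposity / insulin-resistance
   pathway the features measure), the remainder hepatic-direct. The total
   per-allele effect on the latent trait is exactly β_v either way.
2. **Biomarker feedback** (default 0.28): liver-responsive lab features
   additionally reflect the realized trait's direct + idiosyncratic
   component, because liver enzymes are downstream of liver fat.

Without these channels a feature-based predictor would carry zero genetic
signal, contradicting what is observed in real data, where predicted and
true PDFF have nearly equal SNP heritability. The two defaults were
calibrated once, jointly with the signal/residual SDs, to reproduce the
published study conditions — holdout r ≈ 0.66 and AUROC ≈ 0.84 for the
fitted predictor — and then frozen. The realized genetic transfer (the
per-allele effect on the proxy divided by the effect on the latent trait)
is ≈ 0.5 under these defaults; real biobank panels with ~180 features
achieve near-complete transfer, so the synthetic power gain is a
conservative analogue.

### Observation model

The imaging flag is Bernoulli(0.09); true PDFF is revealed only there.
ICD diagnosis is Bernoulli(sensitivity 0.565) among true steatosis cases
that meet cardiometabolic criteria (rate 0.95) and lack exclusionary
diagnoses (rate 0.02); specificity is fixed at 1 by default (the
literature documents underdiagnosis, not over-diagnosis), configurable via
a false-positive rate. Lab-to-imaging time gaps are Uniform(0, 14) years,
and lab features decorrelate from their imaging-day values exponentially
(rate 0.03/yr), so the time-gap weighting scheme has signal to recover.
Features other than the five required ones (BMI, waist circumference, ALT,
AST, triglycerides) are missing completely at random at 10%.

What the generator does **not** emulate: linkage disequilibrium,
relatedness, imputation dosages, ancestry-differential phenotyping or
healthcare access, non-random missingness, and longitudinal feature
trajectories beyond the exponential decay. Passing tests show the
statistical machinery is correct and calibrated under this idealized
model, not that the pipeline is robust to those real-data complications.

## Phenotype prediction

Engine: gradient-boosted trees (LightGBM) with gradient-based one-side
sampling, learning rate 0.01, 60 leaves, minimum leaf population 100, and
up to 750 boosting rounds — scaled down automatically as
min(750, 5n/100) rounds and min(100, n/20) leaf population so desk-scale
fits stay sensible. Validation folds drive early stopping (25 rounds).
No feature selection is performed beyond the trees' own. Weights
w = max(5, g_max/g) floor at 5 as printed in the source formula; a "cap"
mode (min) is exposed because the printed floor is arguably a transcription
of an intended cap. Zero gaps (baseline-visit rows) borrow the smallest
positive gap.

The nested scheme partitions participants into k_outer folds; within the
remaining folds, k_inner rotations of a validation fold give
k_outer × k_inner models. A participant's cohort-wide prediction averages
only models that never saw them in training or validation — for cohort
members that is exactly the k_inner models of their own outer fold.
Participants seen by every model are flagged (n_models = 0), never
silently averaged. Metrics use the percentile bootstrap (1,000 resamples
by default); AUROC uses the midrank convention.

Attribution uses the trees' additive local attributions (per-model
attributions sum to prediction minus baseline); the reported sign is
Spearman's ρ between feature values and attributions.

## Association machinery

- **HWE exact test**: full conditional enumeration over heterozygote
  counts, probabilities ∝ multinomial × 2^het; p sums configurations no
  more probable than observed (tolerance factor 1+10⁻¹²). Verified
  exhaustively against an independent brute-force oracle for all
  configurations up to n = 50.
- **QC**: step-1 rules MAC > 100, MAF ≥ 0.01, call rate > 0.9 (strict),
  HWE p < 10⁻¹⁵ treated as an exclusion (the QC convention; the literal
  keep-only-below reading is available behind a flag). Analysis-specific
  rules: MAF > 0.001 (common replication), MAC ≥ 10 and MAF < 0.01 (rare
  single-variant).
- **LOCO offsets**: blocks of up to 2,000 standardized variants yield
  5-fold cross-validated ridge predictions at penalties {10, 100, 1000};
  a level-1 ridge combines block predictions, refit per left-out
  chromosome. Offsets are structurally invariant to the left-out
  chromosome's genotypes (tested) and enter downstream tests as fixed
  offsets.
- **Single-variant tests**: OLS with covariates for quantitative traits
  (t reference); Firth-penalized logistic regression for binary traits
  with penalized-LRT p-values. The null model for the LRT is fitted with
  the genotype coefficient constrained to zero but the full design's
  Jeffreys penalty (the profile penalized likelihood); comparing
  penalized likelihoods with different penalty dimensions is badly
  anti-conservative. Convergence: penalized score norm < 10⁻⁶, ≤100
  iterations, step-halving. Monomorphic dosages and non-convergent fits
  produce flagged records.
- **Gene masks**: ultra-rare (MAF < 10⁻⁴ in the analyzed sample) PTVs
  (transcript ablation, splice acceptor/donor, stop gained, frameshift)
  and missense variants deleterious by all five predictors; cumulative
  MAC ≥ 10 per gene, dropped genes logged.
- **SKAT**: score statistic Q = Σ_j w_j²(g_jᵀr)² with Beta(1,25) MAF
  weights; null distribution from the eigenvalues of the
  covariate-projected weighted kernel. Mixture-of-χ² p-values use Liu
  moment matching, refined by Imhof numerical inversion when p < 10⁻⁴;
  the inversion is trusted only above ~10⁻¹⁰ (beyond that the integral
  cancels against its 0.5 constant), and the single-eigenvalue case is
  exact. Cross-checked against a 10⁵-draw Monte-Carlo oracle.
- **SKAT-O**: ρ grid {0, 0.01, 0.04, …, 0.81, 1}; minimum p over the grid
  corrected by one-dimensional integration over the shared χ²₁ component
  (128-node Gauss-Legendre on [0, 40]); ρ = 1 mapped to 0.999 inside the
  integration. The construction is mildly conservative (measured type-I
  ≈ 0.03–0.04 at α = 0.05), a known property of min-p unification.
- **ACAT**: T = Σ w_j tan((0.5 − p_j)π)/Σ w_j, p = 0.5 − arctan(T)/π,
  with the small-p linearization tan((0.5−p)π) ≈ 1/(pπ) below 10⁻¹⁶.
- **PVE and power**: the printed PVE formula's MAF terms cancel to
  β²/(β² + N·SE²); power is the noncentral-χ²₁ tail at
  λ = n·q/(1 − q), q = PVE × attenuation, attenuation defaulting to the
  squared proxy-truth correlation for proxy phenotypes.

## Meta-analysis

Primary combination is sample-size-weighted Z (weights √N_eff,
N_eff = 4/(1/cases + 1/controls) for binary cohorts — the convention that
reproduces the published ~9-fold effective-sample-size gain from the
published cohort counts). Z for score/LRT cohorts is recovered as the
signed normal quantile of p/2. Allele mismatches across cohorts are
errors, never silently flipped. IVW effect sizes and Cochran's Q (flagged
at p < 0.10) run alongside; stratified analyses combine cohort results
within each ancestry/sex stratum, then combine strata, with stratum-level
heterogeneity from Q on stratum estimates. Strata without testable
records are omitted with a log entry.

## Post-processing

The plausibility filter retains a proxy-phenotype hit iff it is nominally
(two-sided p < 0.05, no direction requirement) associated with a true
phenotype, or with ≥1 liver enzyme (ALP, ALT, AST, GGT) and ≥2 distinct
metabolic dysfunction markers; the trait vocabularies ship as editable
configuration. Evidence tiers: ≥4 sources → tier 1, 3 → 2, 2 → 3,
≤1 → 4. λ_GC is the median association χ²₁ over the null median 0.4549.

## Problem sizes

The test suite and acceptance script run at desk scale by design: type-I
calibration uses 2,000 null replicates at n = 2,000; λ_GC and p-value
uniformity use 10,000 null variants at n = 4,000; the nested-CV leakage
audit runs the full 10 × 10 scheme at n = 2,000; trait calibration is
checked at n = 50,000; power orderings use 20 seeded replicates. These
sizes make every claim recomputable in minutes while keeping binomial
error bars small relative to the tested bands.

## Known limitations

- No LD: single-variant and gene-level results have no proxy-tagging
  structure, so fine-mapping questions cannot be posed to the simulator.
- SKAT-O's conservatism at moderate α is inherited from the min-p
  construction, not corrected.
- The LOCO ridge is a two-level stacking approximation, not a full
  whole-genome REML fit; it removes polygenic leakage structurally but
  its shrinkage path differs from mixed-model software.
- Genetic transfer into the proxy is partial (≈0.5) under the default
  20-feature panel; real panels are wider and transfer more, so synthetic
  power gains understate the real ones.
- The Firth SE is the penalized-information Wald SE; p-values are LRT
  throughout, so |β/SE| and the p-value disagree slightly by design.
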