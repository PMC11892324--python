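# proxyrare

Rare-variant association testing for metabolic dysfunction-associated
steatotic liver disease (MASLD) is starved of phenotypes: ICD codes miss
roughly 42–45% of true cases, and MRI-derived liver fat (proton density fat
fraction, PDFF) exists for fewer than 10% of biobank participants.
`proxyrare` implements the machine-learning-assisted strategy for this
problem — impute the sparse imaging phenotype from routine clinical
features, then run the rare-variant association machinery on the imputed
("proxy") phenotype over the *whole* cohort — together with everything the
strategy needs around it, exercised end to end on a seeded synthetic
multi-ancestry biobank whose planted effects make every stage verifiable
without restricted data.

The package is aimed at statistical geneticists who want a tested,
desk-scale implementation of this pipeline: for methods work, teaching, or
as a verified reference for the individual statistics.

## What is implemented

**Phenotype imputation** (`proxyrare.predict`). A scikit-learn-style
estimator, `NestedCVRegressor`, fits k_outer × k_inner gradient-boosted
models of log(PDFF) over a nested cross-validation partition (default
10 × 10 = 100 models). Training weights prioritize participants whose lab
measurements are close in time to imaging, w_i = max(5, g_max / g_i) for
time gap g_i. Cohort-wide predictions average only models whose training
and validation sets never contained the participant — leakage-free by
construction and auditable from the membership records. Evaluation (Pearson
r, R², AUROC/AUPRC at the 5.5% steatosis threshold, bootstrap CIs) and
signed additive feature attribution are included.

**Phenotype definition** (`proxyrare.phenotypes`). True MASLD case/control
status from diagnoses with cardiometabolic criteria and exclusionary
diagnoses; predicted case/control status from predicted PDFF (≤4% control,
≥6% case, gray zone excluded); PPV/NPV threshold tables; rank-based
inverse-normal transformation, x → Φ⁻¹((rank − k)/(n − 2k + 1)), Blom
offset k = 3/8.

**Association testing** (`proxyrare.assoc`). Variant QC (MAC/MAF/call
rate/Hardy-Weinberg exact test), leave-one-chromosome-out block-ridge
polygenic offsets, single-variant tests (OLS for quantitative traits;
Firth-penalized logistic regression with penalized-LRT p-values for binary
traits), ultra-rare (MAF < 10⁻⁴) gene masks of PTVs and
all-five-predictor-deleterious missense variants with cumulative MAC ≥ 10,
and the four gene-level tests: BURDEN, SKAT, SKAT-O and ACAT (Cauchy
combination). Per-variant explained variance PVE = β²/(β² + N·SE²) and
noncentral-χ² power, with proxy attenuation by the squared predicted-true
correlation.

**Meta-analysis** (`proxyrare.meta`). Sample-size-and-direction-of-effect
combination Z = Σ√(N_eff,k)·Z_k / √(ΣN_eff,k), with
N_eff = 4/(1/cases + 1/controls) for binary traits; secondary
inverse-variance meta-analysis; Cochran's Q heterogeneity (flagged at
p < 0.10); two-level ancestry- and sex-stratified meta-meta-analysis.

**Post-processing** (`proxyrare.postprocess`). Replication scoring against
known-variant lists, genomic inflation λ_GC, the plausibility filter for
proxy-phenotype hits (nominal association with a true phenotype, or ≥1
liver enzyme and ≥2 metabolic dysfunction markers), and four-tier evidence
grading (≥4 / 3 / 2 / ≤1 sources).

**Synthetic biobank** (`proxyrare.simulate`). A seeded generator producing
a multi-ancestry cohort (EUR 74.3% plus AFR/AMR/SAS/EAS/MID), variants in
three frequency classes with per-ancestry allele frequencies and
ancestry-restricted ultra-rare variants, Hardy-Weinberg genotypes, a latent
log-PDFF trait calibrated to a median PDFF of ~2.9% and ~21% steatosis
prevalence, an imaging subsample (9%), underdiagnosed ICD labels
(sensitivity 0.565), and a JSON truth manifest of every planted effect.

## Worked example

```python
import numpy as np
import proxyrare as pr
from proxyrare import simulate as sim

# 1. a 20,000-participant synthetic biobank with planted effects
data = pr.simulate_dataset(n=20_000, seed=1)

# 2. weighted nested-CV imputation of log(PDFF) in the 9% imaging subsample
imaging = data.phenotypes.index[data.phenotypes["imaging"]]
cols = [n for n, _, _, _ in sim.FEATURE_PANEL] + ["time_gap_years", "age", "sex"]
model = pr.NestedCVRegressor(k_outer=10, k_inner=10, seed=1)
model.fit(data.features.loc[imaging, cols],
          np.log(data.phenotypes.loc[imaging, "true_pdff"]),
          time_gaps=data.features.loc[imaging, "time_gap_years"].to_numpy())

# 3. proxy phenotype for everyone; burden test of a planted causal gene
table = model.predict_table(data.features[cols], timepoint="baseline")
y_proxy = pr.rank_inverse_normal(table["prediction"].to_numpy())
gene, beta_true = next(iter(data.truth.causal_genes.items()))
masks, _ = pr.build_masks(data.variants, data.genotypes.astype(float))
mask = next(m for m in masks if m.gene == gene)
vindex = {v: j for j, v in enumerate(data.variants["variant_id"])}
rec = pr.gene_test(mask, data.genotypes.astype(float), vindex, y_proxy,
                   method="burden")
```

Output (exactly as printed by the evaluation calls around this code):

```
cohort: 20,000 participants, 74.4% EUR
median PDFF 2.87%, steatosis prevalence 21.3%
imaging subsample: 1,855 participants
holdout r = 0.66 (95% CI 0.63-0.68), AUROC = 0.83
GENE0007 (true effect 0.6/allele, cumulative MAC 12):
  proxy burden p = 1.1e-02 (n=20,000)  vs  true-PDFF burden p = 0.44 (n=1,855)
```

The imputed phenotype correlates r = 0.66 with measured log-PDFF in honest
holdout testing. The planted gene — 12 ultra-rare qualifying alleles in
20,000 participants — is invisible in the imaging subsample (p = 0.44) but
nominally detected by the proxy phenotype over the full cohort (p = 0.011):
the sample-size gain outweighs the attenuation from imputation error, which
is the strategy's entire point.

A full pipeline run (`simulate → predict → define-phenotypes → assoc →
meta → report`) is available as `proxyrare run-all --seed 1 --out results/`
or `proxyrare.pipeline.run_pipeline(config)`.

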