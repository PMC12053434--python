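# episcore

DNA-methylation "epi score" modeling for clinical cohorts profiled by
targeted bisulfite sequencing — built around kidney-transplant blood
methylomes, where lymphodepleting induction (anti-thymocyte globulin, ATG),
infection risk, transplant status and age all leave per-CpG signatures.

The package implements, end to end:

* **Reference-based cell-type deconvolution.** Cell-type-specific
  hypomethylated marker regions are called one-vs-all from a reference panel
  of immune-cell methylomes (criteria: span ≥ 500 bp, methylation delta
  ≤ −30 %, BH-adjusted rank-sum FDR < 0.05), and per-sample cell-type
  fractions are estimated by nonnegative least squares on the marker-site
  reference means.
* **The pseudoinverse MMLR epi-score model.** With `M` the sample × site
  methylation matrix and `T` the sample × trait design (age, sex, CMV
  serostatus, ATG, transplant pre/post, infection risk, cell-type PCs,
  ancestry PCs), the multivariate multiple linear regression `M = T·C` is
  fit by the Moore–Penrose pseudoinverse, `C = T⁺·M`, and inverted for
  prediction, `T̂ = M_new·C⁺`. The continuous predicted value of a trait is
  that sample's *epi score* (epi-ATG, epi-infection, EpiAge, …); leave-one-out
  cross-validation guarantees no sample informs its own score. Binary epi
  scores are evaluated by tie-aware AUC, continuous ones by Spearman
  correlation; an L2-penalized logistic regression on raw CpGs is included
  as the baseline classifier.
* **Site-wise association.** Per-CpG OLS of methylation on the full
  covariate design, two-sided t-tests per coefficient, Benjamini–Hochberg
  correction per explanatory variable across sites, and selection of
  trait-associated CpGs (e.g. hypermethylated ATG-associated sites at
  adjusted p < 0.05); plus a Pearson |R| > 0.3, p < 0.05 filter linking
  methylation to gene expression.
* **Outcome models.** Cox proportional hazards (Efron ties) of time to
  infection over a 365-day window on the epi-infection score, restricted to
  CMV-seropositive subjects; Kaplan–Meier display with log-rank test; and
  moderation analysis testing whether factors such as transplant or ATG
  steepen the EpiAge-vs-age slope (epigenetic age acceleration).
* **A synthetic-cohort generator** with complete ground truth (reference
  panels with planted marker blocks, Dirichlet cell mixtures, additive trait
  effects, propensity-driven survival, anticorrelated expression), used by
  every recovery test.

## Worked example

Generate a synthetic cohort at the emulated study scale (90 subjects with
paired pre/post-transplant samples, 8,000 CpGs, six reference cell types)
and run every stage:

```bash
episcore demo --seed 1 --out-dir epidemo
episcore run --config epidemo/config.yaml
```

which prints (abridged):

```
epi_atg_auc: 0.891057
epi_infection_risk_auc: 1.0
epi_age_spearman: 0.965614
n_atg_associated_sites: 102
n_marker_regions: 30
cox_hr: 2.953121
cox_ci: [1.081266, 8.065472]
cox_p: 0.034654
n_expression_pairs_passing: 30
```

Reading the numbers: all 30 planted marker regions are recovered and drive
the cell-fraction covariates; the LOOCV epi-ATG score separates induction
arms with AUC 0.89 (pre-transplant samples of ATG subjects carry the arm
label but not yet the methylation effect, which caps the paired-design AUC);
EpiAge tracks chronological age at ρ = 0.97; 102 CpGs are called
ATG-hypermethylated at adjusted p < 0.05 (100 were planted); and a unit
increase in the epi-infection score nearly triples the infection hazard
within 365 days (HR 2.95, 95 % CI 1.08–8.07). Individual stages are also
available as subcommands (`simulate`, `deconvolve`, `mmlr`, `associate`,
`survive`, `moderate`), and the library surface is scikit-learn-style
(`EpiScoreRegressor`, `MethylDeconvolver`, `RidgeLogisticRegression` expose
`fit`/`predict`/`transform` and compose with sklearn model selection).

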