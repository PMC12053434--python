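# Methods

## The epi-score model

The core model treats the CpG × sample methylation-fraction matrix as a
linear function of sample traits: `M = T·C`, with `T` (samples × traits) the
encoded design and `C` (traits × sites) the per-site trait loadings. Fitting
uses the Moore–Penrose pseudoinverse, `C = T⁺·M`, which is the minimum-norm
least-squares solution per site column; singular values below
`max(dim)·eps·σ_max` are treated as zero (the standard SVD cutoff — the
definition names no tolerance, so the conventional one is used). Prediction
inverts the coefficients the same way, `T̂ = M_new·C⁺`. Because both steps
are plain linear algebra on frozen matrices, a profile never seen in
training receives the same score whether scored alone or in a batch; the
model is therefore portable to external samples.

Key modeling choices:

* **No implicit intercept.** The model as written has none; an explicit
  column of ones is opt-in (`add_intercept=True`, on by default in the
  pipeline config, where it absorbs the baseline methylome instead of
  smearing it across trait columns).
* **Unstandardized traits by default.** Age and PCs enter in their native
  units; `standardize=True` z-scores them and records the scale so
  predictions decode back.
* **Binary traits stay continuous in prediction** — the epi score is the
  predicted value itself, evaluated by tie-aware AUC (normalized
  Mann–Whitney U, ties counted ½). No thresholding is applied anywhere in
  the pipeline.
* **Leave-one-out cross-validation** refits the full model without the
  held-out sample. With paired pre/post samples, the default leaves out the
  whole subject (`group_by_subject`), since a subject's other sample would
  otherwise leak near-duplicate methylome information into its fold.

The group-separation test for epi-score distributions is a two-sided
Mann–Whitney U test (the display in the source design does not name a test;
rank-based is the conservative choice for score distributions). The exact U
null distribution is used for small tie-free samples, the tie-corrected
normal approximation otherwise.

The penalized-logistic baseline (CpGs as covariates, log odds of the trait
as outcome) is L2-penalized — chosen for convexity and a closed IRLS update;
the penalty form was otherwise open — and fit by Newton/IRLS to a gradient
infinity-norm of 1e-6, with the intercept unpenalized and a per-fold inner
grid search available.

## Deconvolution

Marker discovery is one-vs-all: per cell type, per-site delta = mean of that
type's replicates − pooled mean of all other replicates (unweighted pooling,
the simplest reading of one-vs-all). Candidate regions are maximal runs of
consecutive sites with delta ≤ −0.30, allowing inter-site gaps up to 300 bp
(a documented run-gap choice; the original region segmentation tool's
internals are out of scope, so this transparent run-based caller honors the
three stated criteria directly). A region is kept when its span (last −
first position) is ≥ 500 bp and a two-sided rank-sum test of the type's
replicates vs the rest on region-mean methylation survives BH correction at
FDR 0.05 across all candidates of all types. Only hypomethylated markers are
used — the criteria are stated for hypomethylation, and hypomethylated
regions are where a cell type's contribution to the mixture signal is
identifiable.

Fractions solve `min ‖R·f − m‖², f ≥ 0` by NNLS over the union of marker
sites and are renormalized to sum to one by default (raw NNLS sums are
retained, since the coefficients are read as cell-type fractions but need
not sum to one when the reference is incomplete). Collinear reference
profiles trigger a warning — the fit still succeeds but the split among
collinear types is arbitrary. Cell-type covariates for downstream models are
principal components of the fraction matrix (column-centered SVD, sign fixed
so each component's largest-magnitude loading is positive); a k-type
fraction matrix has rank < k, so at most k−1 PCs are allowed.

## Site-wise association

Per CpG: OLS of the methylation fraction on the full covariate design
(intercept, traits, cell-type PCs, ancestry PCs), two-sided t-tests per
coefficient. Methylation is modeled on the fraction scale (no transform was
specified); a logit transform with epsilon-clamping is available. The BH
family is all tested sites for one explanatory variable (per-trait
adjustment — the closest literal reading of adjusting p-values "per
explanatory variable"). Trait-associated sites are two-sided significant
then sign-filtered; one-sided testing before sign filtering would be the
alternative reading and is slightly more powerful, but two-sided + sign is
the implemented, reported behavior. The per-site fits are vectorized (one
shared design factorization), which is exactly equivalent to per-site OLS
and verified against statsmodels in the tests.

## Survival and moderation

The epi-infection score enters a Cox proportional-hazards model of time to
infection continuously; day-resolution times guarantee ties, handled with
the Efron approximation (lower bias than Breslow). The analysis is
restricted to CMV-seropositive subjects by default, over a 365-day window
with censoring at day 365. Each subject is represented by one sample's epi
score — pre-transplant by default, since that score is available before
outcomes accrue. The covariate SD is logged so hazard ratios can be read
per-SD. Kaplan–Meier curves use a median split for display only.

Moderation of epigenetic aging is OLS of EpiAge on age, a binary factor, and
their interaction; the two-sided t-test on the interaction is the moderation
test, and per-group slopes are implied by the combined model (their
difference equals the interaction coefficient exactly).

## The synthetic generator

The generator emulates the study conditions the pipeline is meant for: ~90
subjects sampled pre and post transplant (paired mode) or one sample per
subject (unpaired), an 8,000-CpG targeted panel on a synthetic chromosome
with 100-bp site spacing, six immune reference cell types with four
replicates each, and a 365-day infection follow-up.

* **Reference panel.** A shared baseline methylome is drawn from a mixture
  of two boundary modes (Beta(2,38), Beta(38,2)) and a partially-methylated
  intermediate mode (Beta(8,8), 20 % of sites), as in real CpG methylomes.
  Each cell type gets five planted hypomethylated blocks spanning 600 bp
  where its mean sits 0.40 below the 0.90 background of all other types;
  replicates add beta-distributed noise (concentration 300).
* **Cohort.** Cell fractions are Dirichlet draws (PBMC-like skewed alpha for
  six types); the pre-noise profile is the fraction-weighted mixture of
  cell-type means; additive trait effects are planted at disjoint random
  site sets (defaults: ATG +0.15 at 100 sites, infection risk +0.10 at 100,
  transplant +0.10 at 100, CMV and sex +0.10 at 50 each, a ±0.002/year age
  slope at 200); Gaussian noise (sd 0.05) is added and values clipped to
  [0, 1]. Effects are planted only at sites with headroom for the shift, so
  the injected group difference survives clipping and stays exactly
  recomputable from the recorded ground truth. In paired mode the ATG
  methylation effect applies only to post-transplant samples of ATG-arm
  subjects (induction happens at transplant), while the metadata label is
  the subject-level arm — this deliberate label/effect mismatch mirrors the
  real design and caps the paired-design epi-ATG AUC below what an unpaired
  cohort achieves.
* **Survival.** A latent infection propensity (weighted age, ATG, CMV plus
  unit Gaussian noise) is thresholded at its 70th percentile to label
  infection risk; event times are exponential (or Weibull) with hazard
  `baseline_rate·exp(log_hazard·z)` on the standardized propensity, censored
  at day 365. Defaults: baseline rate 0.002/day, log-hazard ln 2.
* **Expression.** Mapped genes get log-scale expression
  `8 − 4·methylation + N(0, 0.5)`; unmapped genes are pure noise.
* **Determinism.** One root seed expands to per-component streams through
  `numpy.random.SeedSequence` with a fixed registered spawn key per stream,
  so outputs are bit-reproducible and new generators never perturb existing
  streams.

What the generator does *not* emulate — and what passing recovery tests
therefore do not show about real data: read-depth-dependent (beta-binomial)
measurement noise (the emulated matrix is already coverage-filtered, so
Gaussian-then-clip noise is used), spatial correlation of methylation
outside marker blocks, genuine genomic coordinates, cell-composition shifts
caused by treatment (fractions are drawn independently of traits), batch or
ancestry structure in the methylome beyond the recorded covariates, and
confounding between induction arm and transplant timepoint beyond the
paired-design mismatch described above. Real-data performance will be lower
than the recovery numbers; the tests establish correctness of the
machinery, not clinical effect sizes.

## Numerical notes and known behaviors

* Pseudoinverses use LAPACK SVD throughout; rank-deficient designs return
  minimum-norm solutions without error in the MMLR (the site-wise OLS, by
  contrast, refuses rank-deficient designs and names the collinear columns,
  because its t-tests would be meaningless).
* LOOCV scores of a pure-noise (permuted) binary trait center slightly
  *below* AUC 0.5 (typically 0.45–0.48): cross-validated predictions of
  noise labels anti-correlate with held-out truth, a known small-sample
  pessimism of CV. The permutation null is evaluated on the mean over 20
  permutations, which stays well inside 0.5 ± 0.1.
* The DMR caller's region p-value uses a two-sided rank-sum test; direction
  is already enforced by the delta threshold.
* Cell-fraction NNLS can return an all-zero solution for a pathological
  sample; with normalization on, this is a hard "degenerate fit" error
  rather than a silent NaN row.
* Pipeline manifests hash the text artifacts (TSV/BED/JSON); rerunning an
  identical config reproduces them bit-for-bit. Figures (PNG) are display
  output and excluded from the determinism contract.
* Problem sizes in the test-suite recovery loops (2,000-site cohorts, 20–50
  simulation replicates, the 8,000-site epi-score cohort) were chosen as the
  smallest sizes at which the recovery properties are stable and
  statistically interpretable; the full demo scale runs in seconds.
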