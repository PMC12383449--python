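# Methods

## The IVIM signal model and voxelwise fitting

The intravoxel incoherent motion (IVIM) model describes the
diffusion-weighted MR magnitude signal as a two-compartment decay,

    S(b) / S(0) = f · exp(−b·D*) + (1 − f) · exp(−b·D),

with the pure diffusion coefficient `D` (mm²/s) describing tissue water,
the pseudo-diffusion coefficient `D*` (mm²/s) describing incoherent
capillary blood motion, and the perfusion fraction `f` giving the
microvascular share of the voxel signal. The default acquisition scheme
has 12 b-values (0, 10, 25, 50, 75, 100, 150, 200, 400, 800, 1000,
1500 s/mm²): the sub-200 values carry the perfusion information, the
high values pin down `D`. Signals are assumed trace-averaged over
diffusion directions.

Fitting is notoriously ill-conditioned because `D` and `D*` differ by
1–2 orders of magnitude and `f` trades off against both. The per-voxel
procedure is:

1. **Normalization.** Intensities are divided by the voxel's b=0 value.
   `S0` nonetheless remains a free scale in [0.5, 1.5] during
   refinement, so noise in the b=0 point is absorbed rather than
   propagated into `f`.
2. **Segmented initialization.** A log-linear fit on b ≥ 200 s/mm²
   (configurable) gives `D` and an intercept `A`; `f` is initialized as
   `1 − A`.
3. **D\* grid.** Candidate starts for `D*` span 3×10⁻³–0.5 mm²/s on a
   coarse log grid; the start with the lowest residual wins, ties going
   to the lowest `D*` (the grid is ascending and the comparison strict,
   so the choice is deterministic).
4. **Joint refinement.** Bounded trust-region least squares over
   `(D, D*, f, S0)` with `D ∈ [0, 3×10⁻³]`, `D* ∈ [3×10⁻³, 0.5]`,
   `f ∈ [0, 1]`, tight tolerances (1e−14), and per-parameter scaling to
   even out the conditioning. Because refinement is a descent from the
   best grid start, the final residual can never exceed any grid
   candidate's.

Fits with `f < 0` or `f > 0.3` are flagged invalid *after* fitting — an
exclusion rule, not a constraint — because physically implausible
perfusion fractions in brain tissue indicate a noise-dominated fit. The
single validity flag gates aggregation of all three parameter maps.
Background voxels (b=0 intensity below 5% of the volume's
99th-percentile) are masked before fitting.

At SNR 50 (the default phantom noise level) the estimator operates at
the Cramér–Rao floor for this scheme: the bound implies median relative
errors of about 4% for `D`, 11% for `f`, and 28% for `D*`, and the
fitted errors measure at essentially those values. `D*` is intrinsically
the least identifiable parameter; no fitting strategy can do much better
at this noise level, which is why its documented tolerance is the widest.

## Synthetic data

No subject-level data accompany the study conditions this package
emulates, so every pipeline input is generated with known ground truth.

**Phantoms.** Voxels follow the forward model exactly; Rician noise is
applied as the magnitude of the complex signal plus i.i.d. Gaussian
noise of scale σ = S0/SNR in both channels. At zero signal this reduces
to Rayleigh (mean σ√(π/2)), the property the generator tests pin. The
phantom has no anatomy, partial-volume mixing, or artifacts — parameter
recovery results transfer to real data only up to those effects.

**Cohorts.** Two groups of 42 subjects (insomnia-disorder, ID, and
normal control, NC) with 14 regional IVIM features drawn as independent
Gaussians using each group's published mean and SD; demographics (age,
education, BMI as Gaussians; gender as Bernoulli with the observed male
fractions 19/42 and 16/42) and PSQI sleep scores (Gaussian truncated to
the instrument range 0–21 and rounded) likewise follow the published
group moments. Only marginal moments are published, so feature
independence is an assumption, not an inference — it makes the
classification task *harder* than correlated reality in some respects
and easier in others, and classifier results on these cohorts
demonstrate adequacy of the workflow, not clinical performance.

**Perivascular-space grades.** Ordinal 0–4 grades (bands: 0; 1–10;
11–20; 21–40; >40 counted spaces — the published band edges overlap at
10, 20 and 40, so each shared edge is assigned to the lower band) are
generated by thresholding latent severities into counts. The
basal-ganglia latent loads 0.4 on the pooled-standardized PSQI; the
centrum-semiovale latent loads 0.2 on PSQI and 0.2 on standardized
left-thalamus `D*`, realizing a PSQI → thalamic microperfusion →
centrum-semiovale EPVS mediation structure. The loadings were chosen
once to mirror the magnitudes of the reported partial correlations
(≈0.42, 0.23 and 0.34 respectively).

**Mediation test bed.** `M = a·X + ε`, `Y = c′·X + b·M + ε` with
standard-normal `X`, so true ACME = a·b, true ADE = c′ and true total =
a·b + c′. Defaults a=0.5, b=0.4, c′=0.3 give moderate, estimable paths.

All generators are pure functions of (spec, seed).

## Group statistics

Each continuous feature is gated per group by Shapiro–Wilk at α = 0.05:
both groups normal → pooled-variance (Student) two-sample t test;
otherwise Mann–Whitney U, reported as the tie-corrected
normal-approximation Z without continuity correction. The pooled t is
used (rather than Welch) because it reproduces the published reference
statistic at equal group sizes. For small tie-free samples (both groups
n ≤ 8) the Mann–Whitney p is computed exactly from the permutation
distribution; the asymptotic p is used otherwise. Statistic signs follow
the (first − second) group ordering. Categorical tables use Pearson
chi-square without continuity correction. Family-wise adjustment is
Benjamini–Hochberg; classifier screening uses *raw* p < 0.10 — the 0.10
threshold exceeds customary FDR reporting levels, so it is read as a
deliberately liberal pre-filter on unadjusted p (configurable).

## Classification

Screening happens on the whole cohort before the split, mirroring a
screen performed on the published group comparison; this leaks label
information into feature selection and the held-out AUC should be read
accordingly. Subjects are then split 80/20 stratified by group
(per-class training count = round(0.8·n), i.e. 34 + 34 train, 8 + 8
test at n = 42 + 42), features z-scored on training statistics, and an
RBF-kernel SVM trained. The kernel width uses the quantile heuristic
(kernlab `sigest` convention): with K(x,x′) = exp(−σ‖x−x′‖²), σ is the
mean of the 0.1 and 0.9 quantiles of 1/‖x−x′‖² over point pairs (all
pairs when ≤ 5000, a seeded subsample otherwise). The cost parameter is
selected from the doubling grid {0.25, …, 16} by 10-fold stratified
cross-validated accuracy, ties to the smallest cost; if the smaller
class has fewer members than folds the fold count drops to it with a
warning. Held-out metrics: trapezoidal AUC with a DeLong 95% CI
(deterministic; a bootstrap CI would add seed dependence for no gain at
these sizes), and accuracy/sensitivity/specificity at the
decision-function zero threshold with the patient group as positive.
Feature importance is the filter method used for kernel models:
per-feature ROC AUC folded to max(AUC, 1−AUC) and scaled to 0–100,
descending, ties alphabetical.

## Association and mediation

Partial correlation residualizes both variables on the covariates (age,
gender as a 0/1 indicator, education, BMI, plus intercept) by least
squares and correlates the residuals; p from the t transform with
n − k − 2 degrees of freedom. The default is Spearman (the two variables
of interest are rank-transformed first) — consistent with ρ notation and
with ordinal EPVS grades among the targets — with Pearson behind a flag.
Collinear covariate columns are dropped with a warning.

Mediation fits two nested linear models, mediator ~ exposure +
covariates and outcome ~ exposure + mediator + covariates; ACME = a·b,
ADE = c′, and total = ACME + ADE (an exact algebraic identity for nested
OLS with shared covariates, which the tests assert to 1e−12).
Uncertainty comes from a nonparametric bootstrap over subjects (default
500 replicates, seeded): percentile 95% CIs and two-sided p =
2·min(share ≤ 0, share ≥ 0), capped at 1. The resampling bootstrap is
used rather than the quasi-Bayesian Monte-Carlo variant because the
uncertainty statement is about re-drawing subjects. A replicate with a
non-finite fit is redrawn and counted. EPVS grades enter the outcome
model as numeric 0–4 scores, as linear mediation coefficients require.

## Numerical choices and problem sizes

Default problem sizes keep every documented check reproducible on a
laptop: phantoms of 200 voxels for noisy-recovery studies, cohorts of
42 + 42 for classification (25 repetitions when averaging AUC), n = 2000
with 500 bootstrap replicates for mediation recovery. The pipeline
orchestrator fans a single global seed out to per-stage seeds by fixed
offsets so any stage can be rerun in isolation with identical results.

## Known limitations

- Independent-Gaussian cohort features omit inter-regional correlation;
  real-data classifier performance may differ in either direction.
- Phantoms are geometric, noise-only emulations of diffusion MRI; no
  registration, eddy-current or motion effects are modeled, and the
  atlas is assumed aligned upstream.
- The EPVS grade is generated from latent severities, not counted from
  images; only the count → grade mapping is implemented.
- `D*` estimates at clinical SNR carry ~30% median error; group-level
  contrasts remain informative but single-voxel `D*` values should not
  be over-read.
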