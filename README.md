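# ivimid

Analysis pipeline for intravoxel incoherent motion (IVIM)
diffusion-weighted MRI in insomnia research: voxelwise biexponential
fitting, atlas-based region statistics with FDR correction, RBF-SVM
classification of patients vs controls, covariate-adjusted partial
correlation, and bootstrap causal mediation linking sleep quality,
regional microperfusion, and perivascular-space burden. Every input the
pipeline needs can be generated synthetically with known ground truth,
so the whole chain is testable end to end without patient data.

## Who this is for

Neuroimaging researchers who want a tested, scriptable implementation of
the common IVIM group-study workflow — fit, aggregate, compare,
classify, associate, mediate — rather than an in-house one-off, plus
simulation tools for power/recovery checks before acquiring data.

## The model

The IVIM model separates tissue diffusion from capillary
pseudo-diffusion in the multi-b diffusion signal:

    S(b)/S(0) = f·exp(−b·D*) + (1−f)·exp(−b·D)

- `D` — pure diffusion coefficient (mm²/s), microstructure;
- `D*` — pseudo-diffusion coefficient (mm²/s), microcirculation;
- `f` — perfusion fraction, the microvascular signal share.

Voxels are fitted by segmented initialization (monoexponential on
b ≥ 200 s/mm²) followed by bounded nonlinear least squares over
`(D, D*, f, S0)`; fits with `f < 0` or `f > 0.3` are flagged invalid.
Downstream, regional means feed normality-gated t / Mann–Whitney group
tests with Benjamini–Hochberg correction, a p < 0.10 screen feeds an
RBF-kernel SVM (quantile-heuristic sigma, 10-fold CV cost selection,
stratified 80/20 split), and linear mediation with a nonparametric
bootstrap decomposes the sleep-score → perivascular-space association
into direct and microperfusion-mediated parts (ACME = a·b, ADE = c′,
total = ACME + ADE). See `docs/methods.md` for the full account.

## Worked example

Simulate a 42 + 42 cohort whose features follow the published group
moments, classify, and run the mediation analysis:

```sh
ivimid simulate-cohort --n-per-group 42 --seed 1 --out cohort.csv
ivimid classify --cohort cohort.csv --seed 1 --out metrics.json
ivimid mediate  --cohort cohort.csv --nsim 500 --seed 1 --out mediation.json
```

`classify` prints `test AUC 0.922 -> metrics.json`, and `metrics.json`
contains

```json
{
  "auc": 0.921875,
  "auc_ci": [0.762, 1.0],
  "accuracy": 0.75,
  "sensitivity": 0.625,
  "specificity": 0.875,
  "best_cost": 0.5,
  "sigma": 0.049
}
```

— the held-out AUC of 0.92 on 8 + 8 test subjects says the 13 screened
IVIM features separate the synthetic groups well; the DeLong CI is wide
because the test set is small. The mediation output

```
indirect effect 0.0110 (p=0.268)
```

estimates how much of the sleep-score → centrum-semiovale EPVS
association flows through left-thalamus `D*` (per unit PSQI, in grade
units); at n = 84 the indirect path is not individually significant even
though the generator couples it, which is the expected power at this
sample size.

Voxelwise fitting works the same way from the shell
(`ivimid simulate-phantom`, `ivimid fit --dwi … --bvals … --out-prefix …`
producing NIfTI `D`/`D*`/`f`/validity maps), or from Python:

```python
from ivimid import DEFAULT_SCHEME, IVIMParameters, fit_ivim_voxel, ivim_signal

truth = IVIMParameters(d=0.8e-3, d_star=0.02, f=0.15)
signal = ivim_signal(truth, 1.0, DEFAULT_SCHEME.as_array())
fit = fit_ivim_voxel(signal, DEFAULT_SCHEME)   # recovers truth to <1%
```

`ivimid run-all --out-dir out --seed 0` chains every stage on synthetic
inputs and writes a manifest of artifacts and seeds.

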