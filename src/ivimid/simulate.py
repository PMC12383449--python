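"""Synthetic-data generators with known ground truth.

Three generators cover every input the analysis pipeline consumes:

* :func:`generate_phantom` — multi-b diffusion-weighted volumes whose
  voxels follow the biexponential IVIM model with Rician magnitude noise;
* :func:`generate_cohort` — per-subject tables whose regional IVIM
  features, demographics, sleep scores and perivascular-space grades
  follow the published group-level statistics;
* :func:`generate_mediation_data` — exposure/mediator/outcome triples
  from a linear mediation structure with known indirect and direct
  effects.

All generators are pure functions of (spec, seed): identical seeds
reproduce identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference_stats as ref
from .ivim import BValueScheme, IVIMParameters, ivim_signal
from .roi import epvs_grade

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "MediationSpec",
    "generate_phantom",
    "generate_cohort",
    "generate_mediation_data",
    "add_rician_noise",
]


# ---------------------------------------------------------------------------
# DWI phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """A labeled 3-D grid with per-region IVIM ground truth.

    ``snr`` is the ratio of the b=0 signal to the Rician noise scale
    sigma; ``math.inf`` produces a noiseless phantom.
    """

    region_labels: np.ndarray  # 3-D integer array
    truth: dict[int, IVIMParameters]
    snr: float = math.inf
    s0: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        labels = np.asarray(self.region_labels)
        if labels.ndim != 3:
            raise ValueError("region_labels must be 3-D")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")
        missing = set(np.unique(labels)) - set(self.truth)
        if missing:
            raise ValueError(f"labels without ground truth: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(np.asarray(self.region_labels).shape)


def add_rician_noise(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of the complex signal after adding i.i.d. Gaussian noise
    of scale sigma to the real and imaginary channels.

    At zero underlying signal this reduces to a Rayleigh distribution
    with mean sigma*sqrt(pi/2).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return np.asarray(signal, dtype=float).copy()
    g1 = rng.normal(0.0, sigma, size=np.shape(signal))
    g2 = rng.normal(0.0, sigma, size=np.shape(signal))
    return np.hypot(np.asarray(signal) + g1, g2)


def generate_phantom(
    spec: PhantomSpec, scheme: BValueScheme
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Simulate a 4-D multi-b volume from a phantom specification.

    Returns the (X, Y, Z, n_b) signal volume and a dict of 3-D ground-truth
    maps (``d``, ``d_star``, ``f``).
    """
    labels = np.asarray(spec.region_labels)
    b = scheme.as_array()
    volume = np.empty(labels.shape + (b.size,), dtype=float)
    truth_maps = {k: np.empty(labels.shape) for k in ("d", "d_star", "f")}
    for lab in np.unique(labels):
        p = spec.truth[int(lab)]
        where = labels == lab
        volume[where] = ivim_signal(p, spec.s0, b)
        truth_maps["d"][where] = p.d
        truth_maps["d_star"][where] = p.d_star
        truth_maps["f"][where] = p.f
    if math.isfinite(spec.snr):
        rng = np.random.default_rng(spec.seed)
        volume = add_rician_noise(volume, spec.s0 / spec.snr, rng)
    return volume, truth_maps


# ---------------------------------------------------------------------------
# Subject cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of a two-group subject cohort.

    Defaults reproduce the published ID/NC cohort: 42 subjects per group,
    14 regional IVIM features as independent per-group Gaussians,
    demographics and PSQI from the published group moments, and ordinal
    perivascular-space (EPVS) grades driven by latent Gaussians coupled
    to the sleep score (and, for the centrum semiovale, to left-thalamus
    pseudo-diffusion, realizing a mediation structure).
    """

    n_per_group: int = 42
    feature_stats: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: dict(ref.IVIM_FEATURE_STATS)
    )
    demographic_stats: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: dict(ref.DEMOGRAPHIC_STATS)
    )
    male_fraction: dict[str, float] = field(default_factory=lambda: dict(ref.MALE_FRACTION))
    psqi_stats: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(ref.PSQI_STATS))
    #: loading of the basal-ganglia EPVS latent on the standardized PSQI
    bg_psqi_weight: float = 0.4
    #: loadings of the centrum-semiovale EPVS latent on the standardized
    #: PSQI (direct) and on standardized left-thalamus D* (mediated path)
    cso_psqi_weight: float = 0.2
    cso_mediator_weight: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        for name, per_group in {**self.feature_stats, **self.demographic_stats}.items():
            for grp, (_, sd) in per_group.items():
                if sd <= 0:
                    raise ValueError(f"SD must be positive for {name}/{grp}")
        for grp, (_, sd) in self.psqi_stats.items():
            if sd <= 0:
                raise ValueError(f"PSQI SD must be positive for {grp}")


def _truncated_rounded_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int, lo: float, hi: float
) -> np.ndarray:
    """Gaussian draws clipped to the instrument range and rounded to integers."""
    x = rng.normal(mean, sd, n)
    return np.clip(np.round(x), lo, hi).astype(int)


def _epvs_count(latent: np.ndarray) -> np.ndarray:
    """Map a standard-normal latent severity to a non-negative EPVS count.

    The affine map centers typical subjects in the 10-20 band, matching
    the modal grade seen clinically.
    """
    return np.maximum(0, np.round(14.0 + 9.0 * latent)).astype(int)


def generate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Draw a synthetic two-group cohort table.

    Columns: ``subject_id``, ``group`` (ID/NC), ``age``, ``gender``
    (1 = male), ``education``, ``bmi``, ``psqi``, ``bg_epvs`` and
    ``cso_epvs`` (ordinal grades 0-4), plus one column per IVIM feature.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    frames = []
    for grp in ref.GROUPS:
        n = spec.n_per_group
        row: dict[str, np.ndarray] = {}
        row["group"] = np.repeat(grp, n)
        for var, per_group in spec.demographic_stats.items():
            m, s = per_group[grp]
            row[var] = rng.normal(m, s, n)
        row["gender"] = (rng.random(n) < spec.male_fraction[grp]).astype(int)
        m, s = spec.psqi_stats[grp]
        row["psqi"] = _truncated_rounded_normal(rng, m, s, n, 0, 21)
        for feat, per_group in spec.feature_stats.items():
            fm, fs = per_group[grp]
            row[feat] = rng.normal(fm, fs, n)
        frames.append(pd.DataFrame(row))
    table = pd.concat(frames, ignore_index=True)
    table.insert(0, "subject_id", [f"S{i:03d}" for i in range(len(table))])

    # EPVS severity: latent Gaussians coupled to the pooled-standardized
    # sleep score (both sites) and to left-thalamus D* (centrum semiovale
    # only), thresholded into counts and mapped to ordinal grades.
    psqi_mean, psqi_sd = ref.pooled_moments(spec.psqi_stats)
    z_psqi = (table["psqi"].to_numpy() - psqi_mean) / psqi_sd
    n_total = len(table)

    w = spec.bg_psqi_weight
    resid = math.sqrt(max(0.0, 1.0 - w**2))
    bg_latent = w * z_psqi + resid * rng.standard_normal(n_total)
    table["bg_epvs"] = [epvs_grade(c) for c in _epvs_count(bg_latent)]

    if "TLML_Dstar" in spec.feature_stats:
        tm, ts = ref.pooled_moments(spec.feature_stats["TLML_Dstar"])
        z_med = (table["TLML_Dstar"].to_numpy() - tm) / ts
    else:
        z_med = np.zeros(n_total)
    w1, w2 = spec.cso_psqi_weight, spec.cso_mediator_weight
    resid = math.sqrt(max(0.0, 1.0 - w1**2 - w2**2))
    cso_latent = w1 * z_psqi + w2 * z_med + resid * rng.standard_normal(n_total)
    table["cso_epvs"] = [epvs_grade(c) for c in _epvs_count(cso_latent)]
    return table


# ---------------------------------------------------------------------------
# Mediation test bed
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MediationSpec:
    """Linear mediation generator: X -> M -> Y with a direct X -> Y path.

    M = a*X + eps_m and Y = c_prime*X + b*M + eps_y with standard-normal
    X, so the true indirect effect (ACME) is a*b, the true direct effect
    (ADE) is c_prime, and the true total effect is a*b + c_prime.
    """

    a: float = 0.5
    b: float = 0.4
    c_prime: float = 0.3
    noise_sd_m: float = 1.0
    noise_sd_y: float = 1.0
    n: int = 200
    #: number of covariate columns generated independent of (X, M, Y);
    #: adjusting for them tests estimator neutrality
    n_covariates: int = 0
    #: if True, covariates confound X and M (robustness testing)
    confounded: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_m <= 0 or self.noise_sd_y <= 0:
            raise ValueError("noise SDs must be positive")
        if self.n < 10:
            raise ValueError("n must be at least 10")

    @property
    def true_acme(self) -> float:
        return self.a * self.b

    @property
    def true_ade(self) -> float:
        return self.c_prime

    @property
    def true_total(self) -> float:
        return self.a * self.b + self.c_prime


def generate_mediation_data(spec: MediationSpec | None = None) -> pd.DataFrame:
    """Draw (exposure, mediator, outcome) plus optional covariate columns."""
    spec = spec or MediationSpec()
    rng = np.random.default_rng(spec.seed)
    cov = rng.standard_normal((spec.n, spec.n_covariates)) if spec.n_covariates else None
    x = rng.standard_normal(spec.n)
    if spec.confounded and cov is not None:
        x = x + cov.sum(axis=1) * 0.5
    m = spec.a * x + rng.normal(0.0, spec.noise_sd_m, spec.n)
    if spec.confounded and cov is not None:
        m = m + cov.sum(axis=1) * 0.5
    y = spec.c_prime * x + spec.b * m + rng.normal(0.0, spec.noise_sd_y, spec.n)
    out = pd.DataFrame({"exposure": x, "mediator": m, "outcome": y})
    if cov is not None:
        for j in range(spec.n_covariates):
            out[f"cov{j}"] = cov[:, j]
    return out
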