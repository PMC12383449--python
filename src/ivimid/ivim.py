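"""Biexponential intravoxel incoherent motion (IVIM) model and voxelwise fitting.

The IVIM model decomposes the diffusion-weighted MR signal into a slow
tissue-diffusion compartment and a fast pseudo-diffusion compartment
attributed to blood moving through randomly oriented capillaries:

    S(b) / S(0) = f * exp(-b * D*) + (1 - f) * exp(-b * D)

where ``D`` is the pure diffusion coefficient (mm^2/s), ``D*`` the
pseudo-diffusion coefficient (mm^2/s), and ``f`` the perfusion (volume)
fraction of the microvascular compartment.

Fitting proceeds in two stages per voxel: a segmented monoexponential fit
on the high-b-value points initializes ``D`` and ``f``, a small grid over
``D*`` selects the best starting point, and a bounded nonlinear
least-squares refinement of ``(D, D*, f, S0)`` jointly produces the final
estimate.  Voxels whose fitted perfusion fraction falls outside [0, 0.3]
are flagged invalid after fitting (an exclusion rule, not a fit bound).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "BValueScheme",
    "DEFAULT_SCHEME",
    "IVIMParameters",
    "FitConfig",
    "FitResult",
    "VolumeFitResult",
    "ivim_signal",
    "fit_ivim_voxel",
    "apply_f_exclusion",
    "fit_ivim_volume",
    "default_mask",
]


@dataclass(frozen=True)
class BValueScheme:
    """Ordered diffusion weightings (s/mm^2) defining a multi-b acquisition.

    Must contain b = 0, be strictly increasing, and have at least four
    points — the minimum needed to constrain the three IVIM parameters
    plus the b=0 amplitude.
    """

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        arr = np.asarray(vals)
        if arr.size < 4:
            raise ValueError("b-value scheme needs at least 4 values")
        if np.any(arr < 0):
            raise ValueError("b-values must be non-negative")
        if arr[0] != 0.0:
            raise ValueError("scheme must contain b = 0 as its first value")
        if np.any(np.diff(arr) <= 0):
            raise ValueError("b-values must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @classmethod
    def from_file(cls, path) -> "BValueScheme":
        """Read a whitespace-separated one-line b-value file (FSL bval dialect)."""
        with open(path) as fh:
            tokens = fh.read().split()
        return cls(tuple(float(t) for t in tokens))


#: 12-point clinical scheme spanning the perfusion-sensitive low-b range
#: and the diffusion-dominated high-b range.
DEFAULT_SCHEME = BValueScheme((0, 10, 25, 50, 75, 100, 150, 200, 400, 800, 1000, 1500))


@dataclass(frozen=True)
class IVIMParameters:
    """The (D, D*, f) triple for one voxel or region.

    ``d`` and ``d_star`` are in mm^2/s; ``f`` is dimensionless.
    """

    d: float
    d_star: float
    f: float


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the voxelwise fit.

    Bounds keep the solver in the physically plausible range for brain
    tissue; the perfusion-fraction exclusion band is applied after the
    fit rather than as a bound, so out-of-band voxels remain inspectable.
    """

    d_bounds: tuple[float, float] = (0.0, 3e-3)
    d_star_bounds: tuple[float, float] = (3e-3, 0.5)
    f_bounds: tuple[float, float] = (0.0, 1.0)
    s0_bounds: tuple[float, float] = (0.5, 1.5)
    #: b-values at or above this threshold are treated as perfusion-free
    #: in the segmented initialization stage.
    high_b_threshold: float = 200.0
    #: D* starting grid for the nonlinear stage (mm^2/s); ascending so the
    #: lowest-D* start wins residual ties deterministically.
    d_star_grid: tuple[float, ...] = (3e-3, 6e-3, 0.01, 0.02, 0.04, 0.08, 0.15, 0.3, 0.5)
    #: exclusion band for the perfusion fraction, applied post-fit
    f_exclusion: tuple[float, float] = (0.0, 0.3)
    #: voxels whose b=0 intensity is below this fraction of the volume's
    #: 99th-percentile b=0 intensity are masked out (background suppression)
    mask_fraction: float = 0.05


@dataclass(frozen=True)
class FitResult:
    params: IVIMParameters
    s0: float
    residual_norm: float
    converged: bool
    valid: bool = False

    def __post_init__(self) -> None:
        if self.residual_norm < 0:
            raise ValueError("residual_norm must be non-negative")
        if self.valid and not self.converged:
            raise ValueError("a valid fit must have converged")


def ivim_signal(params: IVIMParameters, s0, b):
    """Forward biexponential IVIM signal: s0*[f*exp(-b*D*) + (1-f)*exp(-b*D)].

    ``b`` may be a scalar or array; the prediction lies in (0, s0] for
    f in [0, 1] and non-negative rate constants.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    s0 = float(s0)
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    out = s0 * (
        params.f * np.exp(-b * params.d_star)
        + (1.0 - params.f) * np.exp(-b * params.d)
    )
    return out if out.ndim else float(out)


def _model(theta: np.ndarray, b: np.ndarray) -> np.ndarray:
    d, d_star, f, s0 = theta
    return s0 * (f * np.exp(-b * d_star) + (1.0 - f) * np.exp(-b * d))


def _segmented_init(b: np.ndarray, s: np.ndarray, config: FitConfig) -> tuple[float, float]:
    """Monoexponential log-linear fit on b >= high_b_threshold.

    Returns (D_init, f_init): the slope gives D, and the back-extrapolated
    intercept A satisfies A ≈ 1 - f for a normalized signal.
    """
    hi = (b >= config.high_b_threshold) & (s > 0)
    if hi.sum() < 2:  # degenerate; start flat
        return config.d_bounds[0], 0.05
    slope, intercept = np.polyfit(b[hi], np.log(s[hi]), 1)
    d0 = float(np.clip(-slope, *config.d_bounds))
    f0 = float(np.clip(1.0 - np.exp(intercept), 0.0, 0.6))
    f0 = float(np.clip(f0, *config.f_bounds))
    return d0, f0


def fit_ivim_voxel(intensities, scheme: BValueScheme, config: FitConfig | None = None) -> FitResult:
    """Fit the biexponential IVIM model to one voxel's signal decay.

    The signal is normalized by its b=0 intensity before fitting; S0 is
    still refined as a free scale to absorb noise in the b=0 point.
    Residuals are reported on the normalized scale.
    """
    config = config or FitConfig()
    b = scheme.as_array()
    y = np.asarray(intensities, dtype=float)
    if y.shape != b.shape:
        raise ValueError(f"signal length {y.size} does not match scheme length {b.size}")
    if not np.all(np.isfinite(y)):
        raise ValueError("signal contains non-finite values")
    s0_obs = float(y[0])
    if s0_obs <= 0:
        raise ValueError("b=0 intensity must be positive for a fittable voxel")
    s = y / s0_obs

    d0, f0 = _segmented_init(b, s, config)

    # Grid over D* starts: lowest-residual start wins, ties -> lowest D*
    # because the grid is ascending and the comparison is strict.
    best_cost = np.inf
    best_dstar = config.d_star_grid[0]
    for ds in config.d_star_grid:
        r = _model(np.array([d0, ds, f0, 1.0]), b) - s
        cost = float(r @ r)
        if cost < best_cost:
            best_cost = cost
            best_dstar = ds

    lo = np.array([config.d_bounds[0], config.d_star_bounds[0], config.f_bounds[0], config.s0_bounds[0]])
    hi = np.array([config.d_bounds[1], config.d_star_bounds[1], config.f_bounds[1], config.s0_bounds[1]])
    x0 = np.clip(np.array([d0, best_dstar, f0, 1.0]), lo, hi)
    # D and D* differ by orders of magnitude; x_scale evens out the steps.
    sol = least_squares(
        lambda th: _model(th, b) - s,
        x0,
        bounds=(lo, hi),
        method="trf",
        x_scale=np.array([1e-3, 1e-2, 0.1, 1.0]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=400,
    )
    d, d_star, f, s0_fit = sol.x
    res = _model(sol.x, b) - s
    result = FitResult(
        params=IVIMParameters(d=float(d), d_star=float(d_star), f=float(f)),
        s0=float(s0_fit * s0_obs),
        residual_norm=float(res @ res),
        converged=bool(sol.status > 0),
    )
    return apply_f_exclusion(result, config)


def apply_f_exclusion(result: FitResult, config: FitConfig | None = None) -> FitResult:
    """Flag fits whose perfusion fraction falls outside the accepted band.

    The fitted parameters are left untouched; only ``valid`` changes.
    Fits with f below the lower edge or above the upper edge (default
    band [0, 0.3]) are marked invalid.
    """
    config = config or FitConfig()
    low, high = config.f_exclusion
    f = result.params.f
    ok = (f >= low) and (f <= high) and result.converged
    return replace(result, valid=bool(ok))


def default_mask(volume: np.ndarray, config: FitConfig | None = None) -> np.ndarray:
    """Background mask: keep voxels whose b=0 intensity exceeds a fraction
    of the volume's 99th-percentile b=0 intensity."""
    config = config or FitConfig()
    s0 = volume[..., 0]
    thr = config.mask_fraction * np.percentile(s0, 99)
    return s0 > thr


@dataclass
class VolumeFitResult:
    """Voxelwise parameter maps. Out-of-mask voxels are NaN in the float
    maps and False in both boolean maps."""

    d: np.ndarray
    d_star: np.ndarray
    f: np.ndarray
    s0: np.ndarray
    residual_norm: np.ndarray
    fitted: np.ndarray  # bool: voxel was in-mask and a fit was attempted
    valid: np.ndarray   # bool: fitted and passed the f-exclusion rule

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def n_excluded(self) -> int:
        return int((self.fitted & ~self.valid).sum())

    @property
    def n_masked(self) -> int:
        return int((~self.fitted).sum())


def fit_ivim_volume(
    volume: np.ndarray,
    scheme: BValueScheme,
    mask: np.ndarray | None = None,
    config: FitConfig | None = None,
) -> VolumeFitResult:
    """Fit every in-mask voxel of a 4-D multi-b volume.

    Parameters
    ----------
    volume : (X, Y, Z, n_b) array of signal magnitudes.
    mask : optional boolean (X, Y, Z) array; defaults to the b=0
        intensity threshold mask.
    """
    config = config or FitConfig()
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 4:
        raise ValueError("volume must be 4-D (x, y, z, b)")
    if volume.shape[-1] != len(scheme):
        raise ValueError(
            f"volume has {volume.shape[-1]} b-values, scheme has {len(scheme)}"
        )
    if mask is None:
        mask = default_mask(volume, config)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape[:-1]:
        raise ValueError("mask shape does not match volume spatial shape")

    shape = volume.shape[:-1]
    nan = np.full(shape, np.nan)
    out = VolumeFitResult(
        d=nan.copy(), d_star=nan.copy(), f=nan.copy(), s0=nan.copy(),
        residual_norm=nan.copy(),
        fitted=np.zeros(shape, dtype=bool),
        valid=np.zeros(shape, dtype=bool),
    )
    for idx in zip(*np.nonzero(mask)):
        sig = volume[idx]
        try:
            res = fit_ivim_voxel(sig, scheme, config)
        except ValueError:
            warnings.warn(f"voxel {idx}: unfittable signal, left masked")
            continue
        out.fitted[idx] = True
        out.d[idx] = res.params.d
        out.d_star[idx] = res.params.d_star
        out.f[idx] = res.params.f
        out.s0[idx] = res.s0
        out.residual_norm[idx] = res.residual_norm
        out.valid[idx] = res.valid
    return out
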