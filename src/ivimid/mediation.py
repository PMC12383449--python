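"""Covariate-adjusted partial correlation and linear causal mediation.

Partial correlation residualizes both variables on the covariates (with
an intercept) by least squares and correlates the residuals; the
Spearman variant ranks the two variables of interest first.  The p-value
uses the t transform with n - k - 2 degrees of freedom for k covariates.

Mediation fits two nested linear models — mediator ~ exposure (+
covariates) and outcome ~ exposure + mediator (+ covariates) — and
reports the indirect effect ACME = a*b, the direct effect ADE = c', and
the total effect, with percentile confidence intervals and two-sided
p-values from a nonparametric bootstrap over subjects.  In this linear
setting the point estimates satisfy total = ACME + ADE exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PartialCorrelationResult", "MediationResult", "partial_correlation", "mediate"]


@dataclass(frozen=True)
class PartialCorrelationResult:
    rho: float
    p: float
    df: int
    method: str
    covariates: tuple[str, ...]
    p_fdr: float | None = None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError("rho must lie in [-1, 1]")


@dataclass(frozen=True)
class MediationResult:
    total: float
    total_ci: tuple[float, float]
    total_p: float
    acme: float
    acme_ci: tuple[float, float]
    acme_p: float
    ade: float
    ade_ci: tuple[float, float]
    ade_p: float
    n_sim: int
    n_redrawn: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.total_ci, self.acme_ci, self.ade_ci):
            if lo > hi:
                raise ValueError("CI bounds out of order")


def _design(covariates: pd.DataFrame | np.ndarray | None, n: int) -> tuple[np.ndarray, tuple[str, ...]]:
    """Intercept-plus-covariates design matrix; collinear columns are
    dropped with a warning (rank-revealing QR pivot order)."""
    if covariates is None:
        return np.ones((n, 1)), ()
    if isinstance(covariates, pd.DataFrame):
        names = tuple(covariates.columns)
        c = covariates.to_numpy(dtype=float)
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        names = tuple(f"cov{j}" for j in range(c.shape[1]))
    z = np.column_stack([np.ones(n), c])
    rank = np.linalg.matrix_rank(z)
    if rank < z.shape[1]:
        _, _, piv = _pivoted_qr(z)
        keep = np.sort(piv[:rank])
        dropped = [names[j - 1] for j in piv[rank:] if j > 0]
        warnings.warn(f"dropping collinear covariates: {dropped}")
        z = z[:, keep]
        names = tuple(n_ for j, n_ in enumerate(names) if (j + 1) in keep)
    return z, names


def _pivoted_qr(a: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(a, pivoting=True, mode="economic")
    return q, r, piv


def _residualize(v: np.ndarray, z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(z, v, rcond=None)
    return v - z @ beta


def partial_correlation(
    x,
    y,
    covariates: pd.DataFrame | np.ndarray | None = None,
    method: str = "spearman",
) -> PartialCorrelationResult:
    """Partial correlation of x and y given covariates.

    ``method`` is "spearman" (default; x and y are rank-transformed
    before residualizing) or "pearson".
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    z, cov_names = _design(covariates, n)
    k = z.shape[1] - 1
    if n <= k + 2:
        raise ValueError("need n > number of covariates + 2")
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    rx = _residualize(x, z)
    ry = _residualize(y, z)
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("zero residual variance after covariate adjustment")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    rho_c = min(max(rho, -1.0), 1.0)
    if abs(rho_c) == 1.0:
        p = 0.0
    else:
        t = rho_c * np.sqrt(df / (1.0 - rho_c**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrelationResult(rho=rho_c, p=p, df=df, method=method, covariates=cov_names)


def _mediation_coefs(
    x: np.ndarray, m: np.ndarray, y: np.ndarray, z: np.ndarray
) -> tuple[float, float, float]:
    """(a, b, c') from the two nested OLS fits."""
    zm = np.column_stack([x, z])
    a = np.linalg.lstsq(zm, m, rcond=None)[0][0]
    zy = np.column_stack([x, m, z])
    coef = np.linalg.lstsq(zy, y, rcond=None)[0]
    c_prime, b = coef[0], coef[1]
    return float(a), float(b), float(c_prime)


def _boot_p(draws: np.ndarray) -> float:
    """Two-sided bootstrap p: 2 * min(share <= 0, share >= 0), capped at 1."""
    lo = float((draws <= 0).mean())
    hi = float((draws >= 0).mean())
    return min(1.0, 2.0 * min(lo, hi))


def mediate(
    exposure,
    mediator,
    outcome,
    covariates: pd.DataFrame | np.ndarray | None = None,
    n_sim: int = 500,
    seed: int = 0,
) -> MediationResult:
    """Linear mediation analysis with nonparametric bootstrap uncertainty.

    Point estimates come from the full-sample fits; the bootstrap
    resamples subjects with replacement ``n_sim`` times, refitting both
    models per replicate.  Percentile 95% intervals.  A replicate whose
    fit is non-finite is redrawn (count reported).
    """
    x = np.asarray(exposure, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = x.size
    z, _ = _design(covariates, n)
    k = z.shape[1] - 1
    if n <= k + 3:
        raise ValueError("need n > number of covariates + 3")

    a, b, c_prime = _mediation_coefs(x, m, y, z)
    acme = a * b
    ade = c_prime
    total = acme + ade  # exact linear identity with shared covariates

    rng = np.random.default_rng(seed)
    acme_b = np.empty(n_sim)
    ade_b = np.empty(n_sim)
    n_redrawn = 0
    i = 0
    while i < n_sim:
        idx = rng.integers(0, n, size=n)
        ab, bb, cb = _mediation_coefs(x[idx], m[idx], y[idx], z[idx])
        if not (np.isfinite(ab) and np.isfinite(bb) and np.isfinite(cb)):
            n_redrawn += 1
            if n_redrawn > 10 * n_sim:
                raise RuntimeError("bootstrap failed to produce finite replicates")
            continue
        acme_b[i] = ab * bb
        ade_b[i] = cb
        i += 1
    total_b = acme_b + ade_b

    def ci(draws: np.ndarray) -> tuple[float, float]:
        lo, hi = np.percentile(draws, [2.5, 97.5])
        return float(lo), float(hi)

    return MediationResult(
        total=total, total_ci=ci(total_b), total_p=_boot_p(total_b),
        acme=acme, acme_ci=ci(acme_b), acme_p=_boot_p(acme_b),
        ade=ade, ade_ci=ci(ade_b), ade_p=_boot_p(ade_b),
        n_sim=n_sim, n_redrawn=n_redrawn,
    )
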