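"""Least-squares fitting of the GCSP alpha to empirical attack curves.

The attack curve is resampled onto an equidistant mean-degree grid covering
[0, k_max] (k_max = the intact network's <k>); the single GCSP parameter
alpha is then chosen to minimize the sum of squared residuals between the
resampled P values and the closed-form curve. The objective is cheap, so a
coarse alpha grid scan (step 0.05 across the search bounds) followed by
bounded golden-section refinement is used instead of assuming unimodality.

Resampling uses a step-function convention: the P value assigned to a grid
point is taken from the recorded attack step whose <k> is the smallest
recorded value >= the grid point (no interpolation) — attack curves are
genuine step functions in <k>.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .attack import AttackCurve
from .theory import GCSPParams, gcsp_P

__all__ = [
    "GCSPFit",
    "AlphaFitError",
    "resample_curve",
    "fit_alpha",
    "fit_alpha_points",
    "rank_correlation",
]

DEFAULT_N_POINTS = 20
DEFAULT_BOUNDS = (2.05, 60.0)
COARSE_STEP = 0.05


class AlphaFitError(RuntimeError):
    """Degenerate input for which no alpha fit is defined."""


@dataclass(frozen=True)
class GCSPFit:
    """Result of fitting alpha to one attack curve."""

    alpha_hat: float
    sse: float
    n_points: int
    k_max: float
    property: str = "simulated"


def resample_curve(curve: AttackCurve, n_points: int) -> tuple[np.ndarray, np.ndarray]:
    """Equidistant (mean_degree, P) samples of an attack curve on [0, k_max]."""
    if n_points < 4:
        raise ValueError(f"n_points must be >= 4, got {n_points}")
    if len(curve) < 2:
        raise ValueError("cannot resample a curve with fewer than 2 points")
    grid = np.linspace(0.0, curve.k_max, n_points)
    k_asc = curve.mean_degree[::-1]
    p_asc = curve.giant_fraction[::-1]
    # first recorded <k> at or above each grid point (step-function convention)
    pos = np.searchsorted(k_asc, grid - 1e-12, side="left")
    pos = np.minimum(pos, len(k_asc) - 1)
    return grid, p_asc[pos]


def fit_alpha_points(
    mean_degree: np.ndarray,
    P: np.ndarray,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> tuple[float, float]:
    """Least-squares alpha for raw (mean_degree, P) samples.

    Returns ``(alpha_hat, sse)``. Coarse grid scan then golden-section
    refinement; deterministic for fixed inputs.
    """
    k = np.asarray(mean_degree, dtype=float)
    p = np.asarray(P, dtype=float)
    if np.allclose(p, p[0]):
        raise AlphaFitError("degenerate curve: all P values equal")
    lo, hi = bounds

    alphas = np.arange(lo, hi + COARSE_STEP / 2, COARSE_STEP)
    # one vectorized Lambert-W call over the (alpha, k) product grid
    from scipy.special import lambertw

    c = 2.0 / alphas[:, None] - 1.0
    arg = c * np.exp(c) * np.exp(-k[None, :] / alphas[:, None])
    model = np.clip(1.0 - np.real(lambertw(arg)) / c, 0.0, 1.0)
    sse_grid = ((p[None, :] - model) ** 2).sum(axis=1)
    best = int(np.argmin(sse_grid))

    def objective(alpha: float) -> float:
        resid = p - gcsp_P(k, GCSPParams(alpha=alpha))
        return float(resid @ resid)

    span = (
        max(lo, alphas[best] - 1.5 * COARSE_STEP),
        min(hi, alphas[best] + 1.5 * COARSE_STEP),
    )
    res = optimize.minimize_scalar(
        objective, bounds=span, method="bounded", options={"xatol": 1e-8}
    )
    if res.fun <= sse_grid[best]:
        return float(res.x), float(res.fun)
    return float(alphas[best]), float(sse_grid[best])


def fit_alpha(
    curve: AttackCurve,
    n_points: int = DEFAULT_N_POINTS,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> GCSPFit:
    """Fit the GCSP alpha to one attack curve by least squares."""
    grid, p = resample_curve(curve, n_points)
    try:
        alpha_hat, sse = fit_alpha_points(grid, p, bounds=bounds)
    except AlphaFitError as exc:
        raise AlphaFitError(f"{exc} (property={curve.property})") from exc
    return GCSPFit(
        alpha_hat=alpha_hat,
        sse=sse,
        n_points=n_points,
        k_max=curve.k_max,
        property=curve.property,
    )


def fit_alpha_trajectory(
    trajectory,
    n_points: int = DEFAULT_N_POINTS,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> GCSPFit:
    """Fit alpha to a growth trajectory (kappa, rho) — the time-reversed attack.

    The trajectory is prepended with its empty-network point
    (kappa = 0, rho = 1/N) and resampled with the same step-function
    convention as attack curves.
    """
    if n_points < 4:
        raise ValueError(f"n_points must be >= 4, got {n_points}")
    k_asc = np.concatenate([[0.0], np.asarray(trajectory.kappa, dtype=float)])
    p_asc = np.concatenate(
        [[1.0 / trajectory.N], np.asarray(trajectory.rho, dtype=float)]
    )
    grid = np.linspace(0.0, k_asc[-1], n_points)
    pos = np.minimum(np.searchsorted(k_asc, grid - 1e-12, side="left"), len(k_asc) - 1)
    alpha_hat, sse = fit_alpha_points(grid, p_asc[pos], bounds=bounds)
    return GCSPFit(
        alpha_hat=alpha_hat,
        sse=sse,
        n_points=n_points,
        k_max=float(k_asc[-1]),
        property="simulated",
    )


def rank_correlation(values_a, values_b) -> dict:
    """Spearman rank correlation with tie-corrected ranks.

    Returns ``{"rho": ..., "p_value": ...}``; the p-value is the
    t-approximation used by scipy.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("input vectors must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p_value = stats.spearmanr(a, b)
    return {"rho": float(rho), "p_value": float(p_value)}
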