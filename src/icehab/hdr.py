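"""Highest-density-region closeness to optimal habitat.

For an observation x_n and a fitted mixture density p, define
D_n = {x : p(x) >= p(x_n)} — the region enclosed by the density contour
through x_n — and p_n = P(X in D_n), the probability mass of that
region.  p_n tends to 1 as x_n moves far from all mass, so
c_n = 1 - p_n measures closeness to the high-density ("optimal
habitat") core: c_n = 1 exactly at the global mode, c_n -> 0 in the
tails.

The default estimator is Monte Carlo: draw S samples from the mixture
and count the fraction whose density is at least p(x_n); this is
unbiased with standard error sqrt(p(1-p)/S).  A trapezoidal grid
integrator is provided for d <= 2 as a cross-check, and for a single
Gaussian component the closed form p_n = chi^2_d CDF of the squared
Mahalanobis distance serves as an exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .mixture import VEIMixtureModel

__all__ = ["ClosenessScores", "closeness", "closeness_oracle_single_gaussian"]


@dataclass
class ClosenessScores:
    """HDR containment probability p and closeness c = 1 - p per point."""

    density: np.ndarray  # p(x_n)
    p: np.ndarray  # HDR mass in [0, 1]
    c: np.ndarray  # 1 - p exactly
    mc_se: np.ndarray | None  # Monte-Carlo s.e., None for the grid method
    method: str
    n_samples: int | None
    seed: int | None


def closeness(
    model: VEIMixtureModel,
    points: np.ndarray,
    n_samples: int = 200_000,
    seed: int = 0,
    method: str = "monte_carlo",
    grid_points_per_dim: int = 400,
    grid_halfwidth_sd: float = 9.0,
) -> ClosenessScores:
    """HDR probability p_n and closeness c_n for each point.

    monte_carlo (default, any d): S mixture draws, p_hat = fraction with
    density >= p(x_n); exact density ties count as inside D_n (a
    measure-zero event for continuous models).  grid (d <= 2 only):
    trapezoidal integration of the density over the region above the
    threshold, on a regular grid spanning each component mean plus/minus
    ``grid_halfwidth_sd`` marginal standard deviations.
    """
    if not np.isfinite(model.loglik) and model.n == 0:
        raise ValueError("model must be fitted before computing closeness")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    dens = np.exp(model.log_density(points))

    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        draws = model.sample(n_samples, rng)
        draw_dens = np.sort(np.exp(model.log_density(draws)))
        below = np.searchsorted(draw_dens, dens, side="left")  # strictly < dens
        p = 1.0 - below / n_samples
        se = np.sqrt(p * (1.0 - p) / n_samples)
        return ClosenessScores(density=dens, p=p, c=1.0 - p, mc_se=se,
                               method=method, n_samples=n_samples, seed=seed)

    if method == "grid":
        if model.d > 2:
            raise ValueError("grid integration is supported for d <= 2 only")
        axes = []
        cov = model.covariances()
        for j in range(model.d):
            sd = np.sqrt(cov[:, j])
            lo = np.min(model.means[:, j] - grid_halfwidth_sd * sd)
            hi = np.max(model.means[:, j] + grid_halfwidth_sd * sd)
            axes.append(np.linspace(lo, hi, grid_points_per_dim))
        mesh = np.meshgrid(*axes, indexing="ij")
        grid_pts = np.column_stack([m.ravel() for m in mesh])
        gdens = np.exp(model.log_density(grid_pts))
        # trapezoidal weights: product of per-axis (h, ..., h, h/2 at ends)
        w_total = np.ones(1)
        for ax in axes:
            h = ax[1] - ax[0]
            w = np.full(ax.size, h)
            w[0] = w[-1] = h / 2.0
            w_total = np.multiply.outer(w_total, w)
        weights = w_total.ravel()
        order = np.argsort(gdens)[::-1]
        cum = np.concatenate([[0.0], np.cumsum((gdens * weights)[order])])
        sorted_desc = gdens[order]
        # mass with density >= threshold
        idx = np.searchsorted(-sorted_desc, -dens, side="right")
        p = np.clip(cum[idx], 0.0, 1.0)
        return ClosenessScores(density=dens, p=p, c=1.0 - p, mc_se=None,
                               method=method, n_samples=None, seed=None)

    raise ValueError(f"unknown method {method!r}")


def closeness_oracle_single_gaussian(d: int, mahalanobis_sq: float | np.ndarray) -> np.ndarray | float:
    """Exact HDR mass for one Gaussian.

    For a single Gaussian the region {p(x) >= p(x_n)} is the Mahalanobis
    ellipsoid through x_n, whose mass is the chi-square CDF with d
    degrees of freedom at the squared Mahalanobis distance.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    m2 = np.asarray(mahalanobis_sq, dtype=float)
    if np.any(m2 < 0):
        raise ValueError("mahalanobis_sq must be non-negative")
    out = chi2.cdf(m2, df=d)
    return float(out) if out.ndim == 0 else out
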