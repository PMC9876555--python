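"""Parameter recovery by Kullback-Leibler minimization, plus growth-rate
estimation from cell-count curves.

The division propensity ``alpha`` is recovered from an observed area
sample with the growth increment ``beta`` held fixed at its measured
(or interpolated) value.  The objective is the base-10 KL divergence

    D(P || Q) = sum_x P(x) * log10(P(x) / Q(x))

between the observed histogram P and the forward-model distribution Q
produced by the convolution propagator.  Fitting proceeds in two
stages: an exhaustive coarse scan over a log-spaced ``alpha`` grid,
then a gradient-guided descent on log10(alpha) from the grid minimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator

from .params import GrowthDivisionParams
from .simulate import AreaDistribution, halving_rebin, propagate_distribution, snapshot_distribution

__all__ = [
    "FitConfig",
    "FitResult",
    "GrowthCurve",
    "kl_divergence",
    "kl_gradient",
    "fit_alpha",
    "KLAlphaEstimator",
    "growth_rate_from_curve",
    "interpolate_beta",
]


def _as_probability(p, name: str) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} has negative entries")
    total = arr.sum()
    if total <= 0:
        raise ValueError(f"{name} has zero total mass")
    return arr / total


def kl_divergence(p, q, smooth: float | None = None) -> float:
    """Base-10 KL divergence ``sum P log10(P/Q)``.

    ``smooth`` adds a small constant to Q (then renormalizes) so bins
    where Q vanishes under P mass remain defined; without smoothing such
    bins raise a domain error.
    """
    p = _as_probability(p, "P")
    q = _as_probability(q, "Q")
    if p.shape != q.shape:
        raise ValueError(f"unmatched supports: {p.shape} vs {q.shape}")
    if smooth is not None:
        q = _as_probability(q + smooth, "Q")
    mask = p > 0
    if np.any(q[mask] == 0):
        raise ValueError("Q has zero mass where P > 0; set smooth")
    return float(np.sum(p[mask] * np.log10(p[mask] / q[mask])))


def kl_gradient(p, q, smooth: float | None = None) -> np.ndarray:
    """Per-bin divergence gradient ``4 (P(x) - Q(x)) / Q(x)``."""
    p = _as_probability(p, "P")
    q = _as_probability(q, "Q")
    if p.shape != q.shape:
        raise ValueError(f"unmatched supports: {p.shape} vs {q.shape}")
    if smooth is not None:
        q = _as_probability(q + smooth, "Q")
    if np.any(q == 0):
        raise ValueError("Q has zero-mass bins; set smooth")
    return 4.0 * (p - q) / q


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the two-stage alpha fit."""

    alpha_min: float = 1e-8
    alpha_max: float = 1e-4
    n_grid: int = 50
    histogram_bins: int = 50
    sgd_step: float = 0.15
    sgd_tol: float = 1e-5
    max_sgd_iters: int = 60
    rng_seed: int = 0
    compared_distribution: str = "division_size"
    smooth: float = 1e-12

    def __post_init__(self) -> None:
        if not (0 < self.alpha_min < self.alpha_max):
            raise ValueError("require 0 < alpha_min < alpha_max")
        if self.histogram_bins < 10:
            raise ValueError("need at least 10 histogram bins")
        if self.compared_distribution not in ("division_size", "birth_size", "snapshot"):
            raise ValueError(f"unknown compared_distribution {self.compared_distribution!r}")
        if self.sgd_step <= 0 or self.sgd_tol <= 0:
            raise ValueError("sgd_step and sgd_tol must be positive")


@dataclass
class FitResult:
    """Outcome of one alpha fit."""

    alpha_hat: float
    beta_used: float
    kl_final: float
    n_grid_evals: int
    n_sgd_iters: int
    converged: bool
    on_boundary: bool = False
    grid_alphas: np.ndarray = field(default_factory=lambda: np.array([]))
    grid_kl: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if self.kl_final < 0:
            raise ValueError("KL divergence cannot be negative")


def _model_distribution(alpha: float, beta: float,
                        template: GrowthDivisionParams | None,
                        which: str) -> AreaDistribution:
    if template is None:
        params = GrowthDivisionParams(alpha=alpha, beta=beta)
    else:
        params = replace(template, alpha=alpha, beta=beta)
    div = propagate_distribution(params)
    if which == "division_size":
        return div
    if which == "birth_size":
        return halving_rebin(div)
    return snapshot_distribution(params, division_dist=div)


def fit_alpha(
    observed_areas: np.ndarray,
    beta: float,
    config: FitConfig | None = None,
    params_template: GrowthDivisionParams | None = None,
) -> FitResult:
    """Recover ``alpha`` from an observed area sample at fixed ``beta``.

    Stage 1 evaluates the KL divergence of the observed histogram
    against the propagator's model distribution over a log-spaced alpha
    grid.  Stage 2 descends on log10(alpha) from the grid minimum using
    a finite-difference KL gradient scaled by the magnitude of the
    per-bin divergence gradient, until the KL improvement falls below
    ``sgd_tol``.
    """
    config = config or FitConfig()
    obs = np.asarray(observed_areas, dtype=float)
    obs = obs[np.isfinite(obs)]
    if obs.size < 500:
        raise ValueError(f"need at least 500 observed areas, got {obs.size}")
    if not beta > 0:
        raise ValueError("beta must be positive")

    edges = np.histogram_bin_edges(obs, bins=config.histogram_bins)
    p_obs, _ = np.histogram(obs, bins=edges)
    p_obs = p_obs / p_obs.sum()

    def objective(log_alpha: float) -> float:
        dist = _model_distribution(10.0 ** log_alpha, beta, params_template,
                                   config.compared_distribution)
        q = dist.mass_in(np.clip(edges, dist.edges[0], dist.edges[-1]))
        return kl_divergence(p_obs, q, smooth=config.smooth)

    def model_q(log_alpha: float) -> np.ndarray:
        dist = _model_distribution(10.0 ** log_alpha, beta, params_template,
                                   config.compared_distribution)
        q = dist.mass_in(np.clip(edges, dist.edges[0], dist.edges[-1]))
        q = q + config.smooth
        return q / q.sum()

    grid = np.linspace(math.log10(config.alpha_min),
                       math.log10(config.alpha_max), config.n_grid)
    grid_kl = np.array([objective(g) for g in grid])
    i_min = int(np.argmin(grid_kl))
    on_boundary = i_min in (0, config.n_grid - 1)

    # stage 2: descent on log10(alpha)
    la = grid[i_min]
    best_la, best_kl = la, grid_kl[i_min]
    kl_prev = best_kl
    h = 0.02  # dex, finite-difference half-width
    converged = False
    n_iters = 0
    lo, hi = grid[0], grid[-1]
    for n_iters in range(1, config.max_sgd_iters + 1):
        g = (objective(la + h) - objective(la - h)) / (2 * h)
        scale = 1.0 + float(np.mean(np.abs(kl_gradient(p_obs, model_q(la)))))
        step = -config.sgd_step * g / scale
        step = float(np.clip(step, -0.25, 0.25))
        la = float(np.clip(la + step, lo, hi))
        kl_now = objective(la)
        if kl_now < best_kl:
            best_kl, best_la = kl_now, la
        if abs(kl_now - kl_prev) < config.sgd_tol:
            converged = True
            break
        kl_prev = kl_now

    return FitResult(
        alpha_hat=10.0 ** best_la,
        beta_used=beta,
        kl_final=best_kl,
        n_grid_evals=config.n_grid,
        n_sgd_iters=n_iters,
        converged=converged,
        on_boundary=on_boundary,
        grid_alphas=10.0 ** grid,
        grid_kl=grid_kl,
    )


class KLAlphaEstimator(BaseEstimator):
    """Scikit-learn style estimator for the division propensity ``alpha``.

    Parameters mirror :class:`FitConfig` plus the fixed ``beta``;
    ``fit(X)`` expects the observed areas as a 1-d array or a single
    column and sets ``alpha_``, ``kl_`` and ``result_``.
    """

    def __init__(self, beta: float = 0.3, alpha_min: float = 1e-8,
                 alpha_max: float = 1e-4, n_grid: int = 50,
                 histogram_bins: int = 50, sgd_step: float = 0.15,
                 sgd_tol: float = 1e-5, max_sgd_iters: int = 60,
                 rng_seed: int = 0,
                 compared_distribution: str = "division_size"):
        self.beta = beta
        self.alpha_min = alpha_min
        self.alpha_max = alpha_max
        self.n_grid = n_grid
        self.histogram_bins = histogram_bins
        self.sgd_step = sgd_step
        self.sgd_tol = sgd_tol
        self.max_sgd_iters = max_sgd_iters
        self.rng_seed = rng_seed
        self.compared_distribution = compared_distribution

    def _config(self) -> FitConfig:
        return FitConfig(
            alpha_min=self.alpha_min, alpha_max=self.alpha_max,
            n_grid=self.n_grid, histogram_bins=self.histogram_bins,
            sgd_step=self.sgd_step, sgd_tol=self.sgd_tol,
            max_sgd_iters=self.max_sgd_iters, rng_seed=self.rng_seed,
            compared_distribution=self.compared_distribution,
        )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("expected a single column of areas")
            X = X[:, 0]
        result = fit_alpha(X, self.beta, self._config())
        self.result_ = result
        self.alpha_ = result.alpha_hat
        self.kl_ = result.kl_final
        self.n_features_in_ = 1
        return self


@dataclass
class GrowthCurve:
    """Cell-count time course for one line (replicate wells)."""

    timepoints: np.ndarray  # hours
    counts: np.ndarray      # wells x timepoints, positive integers
    mean_area: float        # um^2

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.counts = np.atleast_2d(np.asarray(self.counts))
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(self.counts < 1):
            raise ValueError("counts must be >= 1")
        if self.counts.shape[1] != self.timepoints.size:
            raise ValueError("counts shape does not match timepoints")


def growth_rate_from_curve(curve: GrowthCurve) -> float:
    """Average growth rate Gr = (2/3) * mean_area / doubling_time.

    The doubling time comes from a log-linear fit of counts against
    time pooled over wells (T_d = ln2 / slope), which is exact on
    noiseless exponentials and robust to count noise.  Units: um^2/hour
    with timepoints in hours.
    """
    t = np.tile(curve.timepoints, curve.counts.shape[0])
    y = np.log(curve.counts.reshape(-1))
    span = curve.counts.max(axis=1) / curve.counts.min(axis=1)
    if np.median(span) < 2.0:
        raise ValueError("counts do not span a doubling")
    slope, _ = np.polyfit(t, y, 1)
    if slope <= 0:
        raise ValueError("non-increasing counts: cannot estimate doubling time")
    doubling_time = math.log(2.0) / slope
    return (2.0 / 3.0) * curve.mean_area / doubling_time


def interpolate_beta(
    mean_area: float,
    measured_pairs: list[tuple[float, float]],
    extrapolation_limit: float = 0.10,
) -> float:
    """Piecewise-linear interpolation of ``beta`` against mean area.

    Exact at measured pairs; beyond the measured range the edge-segment
    slope (clipped to be non-negative) extends the curve up to
    ``extrapolation_limit`` of the range span.
    """
    if not measured_pairs:
        raise ValueError("measured_pairs is empty")
    pairs = sorted(measured_pairs)
    areas = np.array([a for a, _ in pairs], dtype=float)
    betas = np.array([b for _, b in pairs], dtype=float)
    lo, hi = areas[0], areas[-1]
    span = hi - lo if hi > lo else hi
    if mean_area < lo - extrapolation_limit * span or mean_area > hi + extrapolation_limit * span:
        raise ValueError(
            f"query area {mean_area} is more than {extrapolation_limit:.0%} "
            f"beyond the measured range [{lo}, {hi}]"
        )
    if lo <= mean_area <= hi:
        return float(np.interp(mean_area, areas, betas))
    if areas.size == 1:
        return float(betas[0])
    if mean_area < lo:
        slope = max(0.0, (betas[1] - betas[0]) / (areas[1] - areas[0]))
        return float(betas[0] + slope * (mean_area - lo))
    slope = max(0.0, (betas[-1] - betas[-2]) / (areas[-1] - areas[-2]))
    return float(betas[-1] + slope * (mean_area - hi))
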