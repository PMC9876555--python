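"""Analytic laws of the size-control model.

A cell of area ``A`` divides with propensity ``alpha * A**y`` per time
step and otherwise grows.  Under exponential single-cell growth
``A(t) = A_b * exp(k t)`` the waiting time to division has the closed
survival function implemented in :func:`survival_probability`, and the
``y``-th power of the added area is exponentially distributed.  In the
simpler per-cycle ("Poissonian") picture the cycle time and added area
are exponential with rates

    lambda   = -ln(1 - alpha*A_div) / ln 2            (per step)
    lambda_2 = lambda / beta                          (per um^2)

which yield a hypoexponential stationary size distribution with mean
``2x/lambda_2`` and variance ``4x/(3 lambda_2^2)`` for ``x`` cycle
stages, hence a coefficient of variation ``1/sqrt(3x)``.

The iterated division-size map

    t_m(n)     = -ln 2 / ln(1 - alpha*A_div(n))
    A_div(n+1) = A_div(n)/2 + beta * t_m(n)

has a stable fixed point in ``A_div``: the mean size is self-correcting
under size perturbations but shifts when ``alpha`` or the growth rate
changes.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .params import GrowthDivisionParams, RateConstants, SizeMapState

__all__ = [
    "transition_rate",
    "survival_probability",
    "sample_transition_times",
    "cycle_time_rate",
    "added_size_rate",
    "size_distribution_moments",
    "cv_from_stages",
    "stages_from_cv",
    "iterate_size_map",
    "find_fixed_point",
    "proliferation_recovery_curve",
]

LN2 = math.log(2.0)


def transition_rate(params: GrowthDivisionParams, area):
    """Division propensity ``alpha * area**y`` at a given area (per step)."""
    area = np.asarray(area, dtype=float)
    if np.any(area < 0):
        raise ValueError("area must be non-negative")
    out = params.alpha * area ** params.size_exponent
    return float(out) if out.ndim == 0 else out


def _integrated_hazard(t, params: GrowthDivisionParams, birth_area: float) -> np.ndarray:
    """Closed form of the hazard integral under exponential growth.

    integral_0^t alpha * (A_b e^{ks})^gamma ds
      = alpha * A_b^gamma * (e^{k gamma t} - 1) / (k gamma)   for k*gamma != 0
      = alpha * A_b^gamma * t                                 otherwise
    """
    gamma = params.size_exponent
    k = params.k
    if k is None:
        raise ValueError("params.k is required for the exponential-growth law")
    t = np.asarray(t, dtype=float)
    amp = params.alpha * birth_area ** gamma
    kg = k * gamma
    if kg == 0.0:
        return amp * t
    return amp * np.expm1(kg * t) / kg


def survival_probability(t, params: GrowthDivisionParams, birth_area: float):
    """P(no division by time t) for a cell born at ``birth_area``.

    Exponential growth at rate ``k`` with propensity ``alpha*A**gamma``
    gives ``exp(-alpha*A_b^gamma*(e^{k gamma t}-1)/(k gamma))``.  The
    degenerate ``k*gamma = 0`` case reduces to a constant hazard.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    if not birth_area > 0:
        raise ValueError("birth_area must be positive")
    out = np.exp(-_integrated_hazard(t_arr, params, birth_area))
    return float(out) if out.ndim == 0 else out


def sample_transition_times(
    params: GrowthDivisionParams, birth_area: float, n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw division times by inverting the survival function.

    With ``u ~ U(0,1)`` and hazard integral ``H(t)``, ``t = H^{-1}(-ln u)``:
    ``t = ln(1 + k*gamma*E / (alpha*A_b^gamma)) / (k*gamma)`` with
    ``E = -ln u`` standard exponential.  Used as a sampling oracle for the
    exponential added-area law.
    """
    gamma = params.size_exponent
    k = params.k
    if k is None:
        raise ValueError("params.k is required")
    e = rng.exponential(size=n)
    amp = params.alpha * birth_area ** gamma
    kg = k * gamma
    if kg == 0.0:
        return e / amp
    return np.log1p(kg * e / amp) / kg


def _check_probability(params: GrowthDivisionParams, a_div: float) -> float:
    p = params.alpha * a_div
    if not 0.0 < p < 1.0:
        raise ValueError(
            f"alpha*A_div = {p!r} is not a valid per-step division probability"
        )
    return p


def cycle_time_rate(params: GrowthDivisionParams, a_div: float) -> float:
    """Rate of the exponential cycle-time law, -ln(1-alpha*A_div)/ln 2."""
    p = _check_probability(params, a_div)
    return -math.log1p(-p) / LN2


def added_size_rate(params: GrowthDivisionParams, a_div: float) -> RateConstants:
    """Rates (lambda, lambda_2) of the cycle-time and added-area laws.

    ``lambda_2 = -ln(1-alpha*A_div)/(ln2 * A_div * k) = lambda/beta``;
    mean added area is ``1/lambda_2``.
    """
    lam = cycle_time_rate(params, a_div)
    params.check_k(a_div)
    return RateConstants(lambda_cycle=lam, lambda_size=lam / params.beta,
                         beta=params.beta)


def size_distribution_moments(stages_x: float, lambda_size: float) -> tuple[float, float]:
    """Mean ``2x/lambda_2`` and variance ``4x/(3*lambda_2**2)``."""
    if not stages_x > 0 or not lambda_size > 0:
        raise ValueError("stages_x and lambda_size must be positive")
    mean = 2.0 * stages_x / lambda_size
    var = 4.0 * stages_x / (3.0 * lambda_size ** 2)
    return mean, var


def cv_from_stages(stages_x: float) -> float:
    """CV of the stationary size distribution, 1/sqrt(3x)."""
    if not stages_x > 0:
        raise ValueError("stages_x must be positive")
    return 1.0 / math.sqrt(3.0 * stages_x)


def stages_from_cv(cv: float) -> float:
    """Invert CV = 1/sqrt(3x): x = 1/(3 CV^2).  Returns the real value;
    rounding to an integer stage count is the caller's decision."""
    if not cv > 0:
        raise ValueError("cv must be positive")
    return 1.0 / (3.0 * cv * cv)


def _map_step(params: GrowthDivisionParams, a_div: float, beta_mode: str) -> tuple[float, float]:
    p = params.alpha * a_div
    if not 0.0 < p < 1.0:
        raise ValueError("probability overflow")
    t_m = -LN2 / math.log1p(-p)
    if beta_mode == "constant":
        beta_eff = params.beta
    elif beta_mode == "proportional":
        # growth per step re-derived from the fixed k: beta = k * A_div(n)
        beta_eff = params.k_at(a_div) * a_div if params.k is None else params.k * a_div
    else:
        raise ValueError(f"unknown beta_mode {beta_mode!r}")
    return 0.5 * a_div + beta_eff * t_m, t_m


def iterate_size_map(
    params: GrowthDivisionParams,
    a_div_0: float,
    n_generations: int,
    beta_mode: str = "constant",
) -> list[SizeMapState]:
    """Iterate the division-size map for ``n_generations`` generations.

    ``beta_mode='constant'`` uses the measured per-line ``beta`` every
    generation; ``'proportional'`` re-evaluates ``beta = k*A_div(n)``
    from the fixed ``k`` so growth scales with current division size.
    """
    if not a_div_0 > 0:
        raise ValueError("a_div_0 must be positive")
    states: list[SizeMapState] = []
    a = a_div_0
    for n in range(n_generations):
        try:
            a_next, t_m = _map_step(params, a, beta_mode)
        except ValueError as exc:
            raise ValueError(f"size map diverged at generation {n}: {exc}") from exc
        states.append(SizeMapState(a_div=a, t_m=t_m, generation_n=n))
        a = a_next
    return states


def find_fixed_point(
    params: GrowthDivisionParams,
    bracket: tuple[float, float] | None = None,
    rtol: float = 1e-6,
    beta_mode: str = "constant",
) -> float:
    """Area fixed point of the division-size map.

    Solves ``A/2 = beta * ln2 / (-ln(1 - alpha*A))`` by bracketed
    root-finding; the returned ``A*`` satisfies ``|map(A*) - A*| <
    rtol * A*``.
    """
    if bracket is None:
        hi = min(1e6, 0.999999 / params.alpha)
        bracket = (1.0, hi)
    lo, hi = bracket

    def residual(a: float) -> float:
        a_next, _ = _map_step(params, a, beta_mode)
        return a_next - a

    flo, fhi = residual(lo), residual(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"no sign change in bracket ({lo}, {hi}): f(lo)={flo}, f(hi)={fhi}"
        )
    a_star = brentq(residual, lo, hi, xtol=1e-12, rtol=min(rtol, 1e-9))
    return float(a_star)


def proliferation_recovery_curve(
    params: GrowthDivisionParams,
    alpha_step_factor: float,
    n_generations: int,
    beta_mode: str = "constant",
) -> np.ndarray:
    """Mean-cycle-time trajectory after a step change in ``alpha``.

    The map starts at the fixed point of the original parameters; at
    generation 0 ``alpha`` is multiplied by ``alpha_step_factor``.  A
    reduction in ``alpha`` makes ``t_m`` jump up and then decay
    geometrically back toward its new stationary value as growth
    compensates.
    """
    if not alpha_step_factor > 0:
        raise ValueError("alpha_step_factor must be positive")
    a0 = find_fixed_point(params, beta_mode=beta_mode)
    stepped = params.with_alpha(params.alpha * alpha_step_factor)
    states = iterate_size_map(stepped, a0, n_generations, beta_mode=beta_mode)
    return np.array([s.t_m for s in states])
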