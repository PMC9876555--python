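"""Forward generators: agent-based population simulator and the
Fourier-convolution distribution propagator with halving rebin.

Both generators share the same parameters.  The agent simulator evolves
individual cells: every step each cell either divides symmetrically
(with probability ``alpha * A``) or grows by ``beta``.  The propagator
evolves the whole area distribution one generation at a time: the birth
distribution is convolved with an exponential mass-gain distribution to
give the division distribution, which is then rebinned onto halved
areas to give the next generation's birth distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from . import model
from .params import GrowthDivisionParams

__all__ = [
    "SimConfig",
    "AreaDistribution",
    "SimulationResult",
    "run_agent_simulation",
    "halving_rebin",
    "propagate_distribution",
    "snapshot_distribution",
    "total_variation",
]


@dataclass(frozen=True)
class SimConfig:
    """Agent-simulation run configuration."""

    n_initial: int = 1000
    n_final: int = 20000
    rng_seed: int = 0
    max_steps: int = 500_000

    def __post_init__(self) -> None:
        if not (self.n_final > self.n_initial > 0):
            raise ValueError("require n_final > n_initial > 0")


@dataclass
class AreaDistribution:
    """Probability distribution over cell area on a uniform grid.

    ``probabilities[i]`` is the mass of the bin whose left edge is
    ``grid_start + i*grid_step``; bin centres sit half a step right.
    """

    grid_start: float
    grid_step: float
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if np.any(self.probabilities < -1e-12):
            raise ValueError("probabilities must be non-negative")
        total = self.probabilities.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1 (got {total})")

    @property
    def centers(self) -> np.ndarray:
        n = self.probabilities.size
        return self.grid_start + (np.arange(n) + 0.5) * self.grid_step

    @property
    def edges(self) -> np.ndarray:
        n = self.probabilities.size
        return self.grid_start + np.arange(n + 1) * self.grid_step

    def mean(self) -> float:
        return float(np.dot(self.centers, self.probabilities))

    def var(self) -> float:
        m = self.mean()
        return float(np.dot(self.centers ** 2, self.probabilities) - m * m)

    def cv(self) -> float:
        return float(np.sqrt(self.var()) / self.mean())

    def mass_in(self, edges: np.ndarray) -> np.ndarray:
        """Probability mass falling between consecutive ``edges``
        (piecewise-linear interpolation of the CDF within bins)."""
        cdf = np.concatenate([[0.0], np.cumsum(self.probabilities)])
        at = np.interp(edges, self.edges, cdf)
        return np.diff(at)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "area_left_edge": self.edges[:-1],
            "probability": self.probabilities,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AreaDistribution":
        edges = df["area_left_edge"].to_numpy(float)
        step = float(edges[1] - edges[0])
        if not np.allclose(np.diff(edges), step, rtol=1e-9):
            raise ValueError("grid spacing is not uniform")
        return cls(grid_start=float(edges[0]), grid_step=step,
                   probabilities=df["probability"].to_numpy(float))


@dataclass
class SimulationResult:
    """Final-state sample and event log of one agent simulation."""

    areas: np.ndarray
    birth_areas: np.ndarray
    ages: np.ndarray
    division_sizes: np.ndarray
    events: pd.DataFrame
    n_steps: int
    rng_seed: int

    def division_added_sizes(self) -> np.ndarray:
        """Per-event added area: mother's division size minus her birth
        size.  Note divisions still pending at the stop time are absent,
        which censors the largest added sizes; for an unbiased mean use
        :meth:`mean_added_size`."""
        return self.events["mother_area"].to_numpy() - self.events["birth_area"].to_numpy()

    def mean_added_size(self) -> float:
        """Unbiased steady-state mean added area per division.

        Every daughter is born at exactly half her mother's division
        size, so at steady state the mean birth size is half the mean
        division size and the mean added area equals mean division
        size / 2.  This avoids the censoring bias of pairing birth and
        division within the truncated run.
        """
        return float(self.division_sizes.mean()) / 2.0


def run_agent_simulation(
    params: GrowthDivisionParams,
    config: SimConfig,
    division_size_mode: str = "current",
    initial_areas: np.ndarray | None = None,
    fixed_steps: int | None = None,
) -> SimulationResult:
    """Grow a population from ``n_initial`` to ``n_final`` cells.

    Each step, every cell draws ``r ~ U(0,1)``; if ``r < alpha * A`` the
    cell divides symmetrically (mother and daughter each take half of
    the mother's area), otherwise it grows by ``beta``.
    ``division_size_mode`` selects the area entering the division
    probability: ``'current'`` (the live area, default) or ``'frozen'``
    (the cell's last division size, held constant through its cycle).
    ``fixed_steps`` runs exactly that many steps instead of stopping at
    ``n_final`` (useful for degenerate parameter regimes where the
    population cannot grow).  Identical seeds give identical output.
    """
    if division_size_mode not in ("current", "frozen"):
        raise ValueError(f"unknown division_size_mode {division_size_mode!r}")
    rng = np.random.default_rng(config.rng_seed)

    if initial_areas is None:
        # scale set by the map fixed point; only "a random initial area"
        # is prescribed, so start uniform within +/-50% of it
        a_star = model.find_fixed_point(params)
        areas = rng.uniform(0.5, 1.5, config.n_initial) * a_star
    else:
        areas = np.asarray(initial_areas, dtype=float).copy()
        if areas.size != config.n_initial:
            raise ValueError("initial_areas length must equal n_initial")
    birth = areas.copy()
    adiv = 2.0 * areas  # notional last division size for frozen mode
    ages = np.zeros(areas.size, dtype=np.int64)
    born_at = np.zeros(areas.size, dtype=np.int64)

    ev_step: list[np.ndarray] = []
    ev_mother: list[np.ndarray] = []
    ev_birth: list[np.ndarray] = []
    ev_born_at: list[np.ndarray] = []

    step = 0
    while (step < fixed_steps if fixed_steps is not None
           else areas.size < config.n_final):
        step += 1
        if step > config.max_steps:
            raise RuntimeError(
                f"population did not reach {config.n_final} cells within "
                f"{config.max_steps} steps"
            )
        basis = areas if division_size_mode == "current" else adiv
        p = params.alpha * basis
        bad = p >= 1.0
        if np.any(bad):
            raise ValueError(
                "per-step division probability >= 1 at area "
                f"{float(basis[bad][0])}"
            )
        divide = rng.random(areas.size) < p
        if divide.any():
            mothers = areas[divide].copy()
            ev_step.append(np.full(mothers.size, step, dtype=np.int64))
            ev_mother.append(mothers)
            ev_birth.append(birth[divide].copy())
            ev_born_at.append(born_at[divide].copy())
            half = mothers / 2.0
            areas[divide] = half
            birth[divide] = half
            adiv[divide] = mothers
            ages[divide] = 0
            born_at[divide] = step
            areas = np.concatenate([areas, half])
            birth = np.concatenate([birth, half])
            adiv = np.concatenate([adiv, mothers])
            ages = np.concatenate([ages, np.zeros(half.size, dtype=np.int64)])
            born_at = np.concatenate(
                [born_at, np.full(half.size, step, dtype=np.int64)])
            grew = ~divide
            areas[: grew.size][grew] += params.beta
            ages[: grew.size][grew] += 1
        else:
            areas += params.beta
            ages += 1

    if ev_mother:
        events = pd.DataFrame({
            "step": np.concatenate(ev_step),
            "mother_area": np.concatenate(ev_mother),
            "birth_area": np.concatenate(ev_birth),
            "birth_step": np.concatenate(ev_born_at),
        })
    else:
        events = pd.DataFrame({
            "step": np.array([], dtype=np.int64),
            "mother_area": np.array([], dtype=float),
            "birth_area": np.array([], dtype=float),
            "birth_step": np.array([], dtype=np.int64),
        })
    return SimulationResult(
        areas=areas, birth_areas=birth, ages=ages,
        division_sizes=events["mother_area"].to_numpy().copy(),
        events=events, n_steps=step, rng_seed=config.rng_seed,
    )


def halving_rebin(dist: AreaDistribution) -> AreaDistribution:
    """Map a division-size distribution to the birth-size distribution.

    Bin ``x`` of the output collects bins ``2x`` and ``2x+1`` of the
    input (areas halved onto the same grid step); mass is conserved
    exactly and the grid step is unchanged.  Odd-length inputs are
    zero-padded.  The output keeps the input's bin count with zeros in
    the vacated upper half, so it can be convolved on the same grid.
    """
    if dist.grid_start != 0.0:
        raise ValueError("halving rebin requires a grid starting at 0")
    p = dist.probabilities
    if p.size % 2:
        p = np.append(p, 0.0)
    folded = p[0::2] + p[1::2]
    out = np.zeros(dist.probabilities.size)
    out[: folded.size] = folded
    return AreaDistribution(grid_start=0.0, grid_step=dist.grid_step,
                            probabilities=out)


def _gain_distribution(lambda_size: float, n_bins: int, step: float) -> np.ndarray:
    """Exponential added-area law discretized on the grid (exact bin mass)."""
    edges = np.arange(n_bins + 1) * step
    mass = np.exp(-lambda_size * edges[:-1]) - np.exp(-lambda_size * edges[1:])
    return mass / mass.sum()


def propagate_distribution(
    params: GrowthDivisionParams,
    n_bins: int = 4096,
    grid_step: float | None = None,
    n_generations: int | None = None,
    tol: float = 1e-6,
    return_history: bool = False,
    boundary_mass_limit: float = 1e-3,
):
    """Iterate the convolution/halving propagator to its stationary law.

    Generation 0 is a delta at ``k/alpha`` (the expected mean added
    area, with ``k = beta/A*`` when unset).  Each generation the birth
    distribution is convolved (FFT, linear semantics) with the
    exponential gain distribution of rate ``lambda_2`` to produce the
    division distribution; the next birth distribution is its halving
    rebin.  Iteration stops when the L1 distance between successive
    division distributions drops below ``tol`` or after
    ``n_generations``.

    Returns the converged division-size :class:`AreaDistribution` (or
    the full history when ``return_history``).
    """
    a_star = model.find_fixed_point(params)
    rates = model.added_size_rate(params, a_star)
    lam2 = rates.lambda_size
    if grid_step is None:
        # converged mean (= A*) near bin 1000
        grid_step = a_star / 1000.0
    # require grid to cover >= 6 means of the gain distribution
    if n_bins * grid_step < 6.0 / lam2:
        raise ValueError("grid covers fewer than 6 gain-distribution means")

    gain = _gain_distribution(lam2, n_bins, grid_step)
    k = params.k if params.k is not None else params.beta / a_star
    delta_loc = min(int((k / params.alpha) / grid_step), n_bins - 1)
    birth = np.zeros(n_bins)
    birth[delta_loc] = 1.0

    history: list[AreaDistribution] = []
    prev: np.ndarray | None = None
    max_gen = n_generations if n_generations is not None else 10_000
    for gen in range(max_gen):
        division = fftconvolve(birth, gain)[:n_bins]
        division = np.clip(division, 0.0, None)
        lost = 1.0 - division.sum()
        if lost > boundary_mass_limit:
            raise ValueError(
                f"grid too small: {lost:.2%} of mass beyond the boundary "
                f"at generation {gen}"
            )
        division /= division.sum()
        dist = AreaDistribution(0.0, grid_step, division)
        if return_history:
            history.append(dist)
        if prev is not None and np.abs(division - prev).sum() < tol:
            break
        prev = division
        birth = halving_rebin(dist).probabilities
    return history if return_history else dist


def snapshot_distribution(
    params: GrowthDivisionParams,
    division_dist: AreaDistribution | None = None,
    max_age_factor: float = 8.0,
) -> AreaDistribution:
    """Approximate steady-state population snapshot distribution.

    Built from the stationary birth distribution (halved division
    distribution): a cell born at area ``b`` is observed at age ``t``
    with weight ``2^(-t/t_m) * prod_{s<t}(1 - alpha*(b + beta*s))``
    (exponential-growth age bias times survival under the current-area
    hazard) and has area ``b + beta*t``.
    """
    if division_dist is None:
        division_dist = propagate_distribution(params)
    birth = halving_rebin(division_dist)
    a_star = model.find_fixed_point(params)
    t_m = 1.0 / model.cycle_time_rate(params, a_star)
    step = birth.grid_step
    n = birth.probabilities.size
    centers = birth.centers
    max_age = int(max_age_factor * t_m)
    # ages sampled at grid-step resolution in area: t such that beta*t = j*step
    ages = np.arange(0, max_age, max(1, int(round(step / params.beta))))
    out = np.zeros(n)
    alive_mask = birth.probabilities > 1e-14
    for b, w in zip(centers[alive_mask], birth.probabilities[alive_mask]):
        a_t = b + params.beta * ages
        hazard = np.clip(params.alpha * a_t, 0.0, 1.0)
        survival = np.concatenate([[1.0], np.cumprod(1.0 - hazard[:-1])])
        weight = w * survival * np.exp2(-ages / t_m)
        idx = np.minimum((a_t / step).astype(int), n - 1)
        np.add.at(out, idx, weight)
    out /= out.sum()
    return AreaDistribution(0.0, step, out)


def total_variation(d1: AreaDistribution, d2: AreaDistribution) -> float:
    """Total-variation distance between two distributions on the same grid."""
    if (d1.grid_start != d2.grid_start or d1.grid_step != d2.grid_step
            or d1.probabilities.size != d2.probabilities.size):
        raise ValueError("distributions must share a grid")
    return 0.5 * float(np.abs(d1.probabilities - d2.probabilities).sum())
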