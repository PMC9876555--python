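"""Seeded generators for every input the pipeline consumes.

The generators emulate a melanoma-like cell-line panel: per-line
single-cell area distributions are produced by the agent-based
size-control simulator at parameters drawn from the measured envelope
(alpha log-uniform in [6.38e-7, 3.67e-6] P/um^2, beta uniform in
[0.16, 0.60] um^2/min); omics matrices carry planted sub-/super-scaling
features under multiplicative lognormal noise; growth curves follow
exponential count growth at each line's simulated division rate.
Every generator is a pure function of its seed and emits a ground-truth
table sufficient to score downstream hit calling exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import model
from .fitting import GrowthCurve
from .params import GrowthDivisionParams
from .scaling import effect_size_matrix
from .simulate import SimConfig, run_agent_simulation

__all__ = [
    "PanelSpec",
    "OmicsSpec",
    "Panel",
    "make_panel",
    "make_omics",
    "make_growth_curves",
]

ALPHA_RANGE = (6.38e-7, 3.67e-6)   # P/um^2, measured panel envelope
BETA_RANGE = (0.16, 0.60)          # um^2/min

GENOTYPES = ("BRAF", "NRAS", "BRAFKD/NRAS")


@dataclass(frozen=True)
class PanelSpec:
    """Specification of a synthetic cell-line panel."""

    n_lines: int = 11
    alpha_range: tuple[float, float] = ALPHA_RANGE
    beta_range: tuple[float, float] = BETA_RANGE
    cells_per_line: int = 1500
    explicit_params: tuple[tuple[float, float], ...] | None = None
    n_measured_beta: int = 6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha_range[0] <= 0 or self.beta_range[0] <= 0:
            raise ValueError("parameter ranges must be positive")
        if self.n_lines <= 0 or self.cells_per_line <= 0:
            raise ValueError("n_lines and cells_per_line must be positive")


@dataclass(frozen=True)
class OmicsSpec:
    """Specification of synthetic omics matrices with planted structure."""

    n_features: int = 1000
    fraction_sub: float = 0.05
    fraction_super: float = 0.05
    effect_size: float = 2.0
    noise_cv: float = 0.2
    coupling: tuple[float, float, float] = (0.6, 0.3, 0.1)  # uncoupled/pos/neg
    coupling_noise_cv: float = 0.1
    n_phospho: int | None = None
    scaling_exponent: float | None = None  # None: calibrated to effect_size
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_sub + self.fraction_super <= 1:
            raise ValueError("planted fractions must sum to <= 1")
        if self.effect_size <= 1:
            raise ValueError("effect size must exceed 1")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be non-negative")
        if abs(sum(self.coupling) - 1.0) > 1e-9:
            raise ValueError("coupling mixture must sum to 1")


@dataclass
class Panel:
    """A synthetic panel: metadata table plus per-line area samples."""

    table: pd.DataFrame           # line_id-indexed metadata incl. truth
    areas: dict[str, np.ndarray]  # single-cell areas per line
    rng_seed: int

    @property
    def line_ids(self) -> list[str]:
        return list(self.table.index)


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def make_panel(spec: PanelSpec) -> Panel:
    """Simulate a cell-line panel with known (alpha, beta) ground truth.

    Per-line areas come from the agent simulator (population snapshot);
    size classes come from common-language effect-size clustering.
    Line ids, genotype labels and the measured-beta flags are synthetic
    metadata mirroring the panel layout (beta measured for the first
    ``n_measured_beta`` lines).
    """
    rng = np.random.default_rng(spec.rng_seed)
    if spec.explicit_params is not None:
        pairs = list(spec.explicit_params)
        if len(pairs) != spec.n_lines:
            raise ValueError("explicit_params length must equal n_lines")
    else:
        la = rng.uniform(math.log(spec.alpha_range[0]),
                         math.log(spec.alpha_range[1]), spec.n_lines)
        betas = rng.uniform(*spec.beta_range, spec.n_lines)
        pairs = [(float(math.exp(a)), float(b)) for a, b in zip(la, betas)]

    areas: dict[str, np.ndarray] = {}
    rows = []
    for i, (alpha, beta) in enumerate(pairs):
        line = f"L{i + 1:02d}"
        params = GrowthDivisionParams(alpha=alpha, beta=beta)
        config = SimConfig(
            n_initial=max(50, spec.cells_per_line // 10),
            n_final=spec.cells_per_line,
            rng_seed=int(rng.integers(2 ** 31 - 1)),
        )
        result = run_agent_simulation(params, config)
        areas[line] = result.areas
        rows.append({
            "line_id": line,
            "mean_area_um2": float(result.areas.mean()),
            "area_sd": float(result.areas.std(ddof=1)),
            "genotype": GENOTYPES[i % len(GENOTYPES)],
            "measured_beta": i < spec.n_measured_beta,
            "true_alpha": alpha,
            "true_beta": beta,
        })
    table = pd.DataFrame(rows).set_index("line_id")
    classes = effect_size_matrix(areas, n_classes=min(3, spec.n_lines)).classes
    table["size_class"] = classes
    return Panel(table=table, areas=areas, rng_seed=spec.rng_seed)


def _calibrated_exponent(areas: np.ndarray, split: float, effect: float,
                         sign: float) -> float:
    """Exponent s with mean(area^s | large)/mean(area^s | small) = effect^sign."""
    large = areas[areas > split]
    small = areas[areas <= split]

    def ratio(s: float) -> float:
        return float(np.mean(large ** s) / np.mean(small ** s)) - effect ** sign

    return brentq(ratio, -30.0, 30.0)


def _planted_profile(areas: np.ndarray, split: float, exponent: float) -> np.ndarray:
    prof = areas ** exponent
    return prof / prof.mean() * 100.0


def make_omics(
    spec: OmicsSpec, panel: Panel
) -> dict[str, pd.DataFrame]:
    """Generate peptide, phosphopeptide and transcript matrices.

    Null features are lognormal noise about 100 scaled units; planted
    sub-/super-scaling features follow a power law in line mean area
    whose exponent is calibrated so the large/small group ratio equals
    the spec effect size.  Phosphopeptides are generated per parent
    peptide with independent planted adjusted-abundance effects;
    transcripts derive from peptides through the coupling mixture
    (uncoupled / positive / negative).  Returns a dict with keys
    ``peptides``, ``phospho``, ``phospho_parent``, ``transcripts``,
    ``truth``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    lines = panel.line_ids
    mean_areas = panel.table["mean_area_um2"].to_numpy(float)
    split = float(mean_areas.mean())
    if not (np.any(mean_areas > split) and np.any(mean_areas <= split)):
        raise ValueError("panel areas do not straddle their mean; cannot plant effects")

    n = spec.n_features
    n_sub = int(round(n * spec.fraction_sub))
    n_super = int(round(n * spec.fraction_super))
    labels = np.array(["null"] * n, dtype=object)
    labels[:n_sub] = "sub"
    labels[n_sub:n_sub + n_super] = "super"
    rng.shuffle(labels)

    if spec.scaling_exponent is None:
        s_super = _calibrated_exponent(mean_areas, split, spec.effect_size, +1.0)
        s_sub = _calibrated_exponent(mean_areas, split, spec.effect_size, -1.0)
    else:
        s_super = abs(spec.scaling_exponent)
        s_sub = -abs(spec.scaling_exponent)

    base = np.empty((n, len(lines)))
    for i, lab in enumerate(labels):
        if lab == "sub":
            base[i] = _planted_profile(mean_areas, split, s_sub)
        elif lab == "super":
            base[i] = _planted_profile(mean_areas, split, s_super)
        else:
            base[i] = 100.0
    noise = _lognormal_noise(rng, spec.noise_cv, base.shape)
    pep_ids = [f"pep{i:05d}" for i in range(n)]
    peptides = pd.DataFrame(base * noise, index=pep_ids, columns=lines)

    # phosphopeptides: one site per parent for the first n_phospho parents
    n_ph = spec.n_phospho if spec.n_phospho is not None else n // 2
    n_ph = min(n_ph, n)
    parent_idx = rng.choice(n, size=n_ph, replace=False)
    ph_labels = np.array(["null"] * n_ph, dtype=object)
    n_ph_sub = int(round(n_ph * spec.fraction_sub))
    n_ph_super = int(round(n_ph * spec.fraction_super))
    ph_labels[:n_ph_sub] = "sub"
    ph_labels[n_ph_sub:n_ph_sub + n_ph_super] = "super"
    rng.shuffle(ph_labels)
    ph_base = np.empty((n_ph, len(lines)))
    for i, lab in enumerate(ph_labels):
        stoich = np.ones(len(lines))
        if lab == "sub":
            stoich = _planted_profile(mean_areas, split, s_sub) / 100.0
        elif lab == "super":
            stoich = _planted_profile(mean_areas, split, s_super) / 100.0
        ph_base[i] = peptides.iloc[parent_idx[i]].to_numpy() * stoich
    ph_noise = _lognormal_noise(rng, spec.noise_cv, ph_base.shape)
    ph_ids = [f"pep{parent_idx[i]:05d}_p{i:05d}" for i in range(n_ph)]
    phospho = pd.DataFrame(ph_base * ph_noise, index=ph_ids, columns=lines)
    parent_map = pd.Series([pep_ids[j] for j in parent_idx], index=ph_ids,
                           name="parent")

    # transcripts: coupling mixture relative to peptides
    coupling = rng.choice(["uncoupled", "positive", "negative"], size=n,
                          p=list(spec.coupling))
    tr_base = np.empty((n, len(lines)))
    logp = np.log(peptides.to_numpy(float))
    for i, c in enumerate(coupling):
        if c == "positive":
            tr_base[i] = peptides.iloc[i].to_numpy()
        elif c == "negative":
            # geometric reflection about the row's log-mean
            tr_base[i] = np.exp(2.0 * logp[i].mean() - logp[i])
        else:
            tr_base[i] = 100.0 * _lognormal_noise(rng, spec.noise_cv, len(lines))
    tr_noise = _lognormal_noise(rng, spec.coupling_noise_cv, tr_base.shape)
    transcripts = pd.DataFrame(tr_base * tr_noise, index=pep_ids, columns=lines)

    truth = pd.DataFrame({
        "feature": pep_ids,
        "scaling": labels,
        "coupling": coupling,
    }).set_index("feature")
    truth_ph = pd.DataFrame({
        "feature": ph_ids,
        "scaling": ph_labels,
        "parent": parent_map.to_numpy(),
    }).set_index("feature")

    return {
        "peptides": peptides,
        "phospho": phospho,
        "phospho_parent": parent_map,
        "transcripts": transcripts,
        "truth": truth,
        "truth_phospho": truth_ph,
    }


def make_growth_curves(
    panel: Panel,
    timestep_h: float = 4.0,
    duration_h: float = 72.0,
    count_noise_cv: float = 0.05,
    n_wells: int = 3,
    n0: int = 200,
    rng_seed: int | None = None,
) -> tuple[dict[str, GrowthCurve], pd.DataFrame]:
    """Exponential growth-count curves at each line's division rate.

    The true doubling time is the mean cycle time at the line's map
    fixed point (minutes, converted to hours); counts follow
    ``n0 * 2^(t/T_d)`` with multiplicative lognormal noise, rounded to
    integers >= 1.  Returns the curves and a truth table with T_d and
    the implied growth rate Gr = (2/3) * mean_area / T_d.
    """
    seed = panel.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed + 7919)
    t = np.arange(0.0, duration_h + 1e-9, timestep_h)
    curves: dict[str, GrowthCurve] = {}
    rows = []
    for line in panel.line_ids:
        alpha = float(panel.table.loc[line, "true_alpha"])
        beta = float(panel.table.loc[line, "true_beta"])
        params = GrowthDivisionParams(alpha=alpha, beta=beta)
        a_star = model.find_fixed_point(params)
        t_d_h = (1.0 / model.cycle_time_rate(params, a_star)) / 60.0
        ideal = n0 * np.exp2(t / t_d_h)
        if count_noise_cv > 0:
            counts = np.maximum(
                1, np.rint(ideal * _lognormal_noise(rng, count_noise_cv,
                                                    (n_wells, t.size)))
            ).astype(int)
        else:
            # exact exponential law (no integer rounding) so the
            # noiseless round trip is exact
            counts = np.tile(ideal, (n_wells, 1))
        mean_area = float(panel.table.loc[line, "mean_area_um2"])
        curves[line] = GrowthCurve(timepoints=t, counts=counts,
                                   mean_area=mean_area)
        rows.append({
            "line_id": line,
            "true_doubling_time_h": t_d_h,
            "true_gr": (2.0 / 3.0) * mean_area / t_d_h,
        })
    truth = pd.DataFrame(rows).set_index("line_id")
    return curves, truth
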