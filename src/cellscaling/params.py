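"""Model parameters for the stochastic size-control model.

The model describes a population of cells that grow by a fixed area
increment per time step (one step = one minute) and divide symmetrically
with a propensity proportional to a power of their current area.  Two
constants govern the dynamics: the division propensity ``alpha``
(probability per unit area per step, printed units P/um^2) and the
growth increment ``beta`` (um^2 per minute).  ``beta`` may equivalently
be expressed through the specific growth constant ``k`` via
``beta = k * A_div`` where ``A_div`` is the division area.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path


@dataclass(frozen=True)
class GrowthDivisionParams:
    """Constants of the growth/division model.

    Parameters
    ----------
    alpha : float
        Division propensity per unit area per time step (P/um^2).
    beta : float
        Area gained per time step (um^2/min); one step is one minute.
    k : float or None
        Specific growth constant with ``beta = k * A_div``.  Optional;
        when both ``k`` and a division area are known the identity is
        checked to 1e-9 relative tolerance by :meth:`check_k`.
    size_exponent : float
        The power ``y`` (also written gamma) in the transition rate
        ``alpha * A**y``; default 1 (propensity linear in area).
    stages_x : float
        Number of effective cell-cycle stages (positive real; rounded
        by callers when an integer stage count is required).
    """

    alpha: float
    beta: float
    k: float | None = None
    size_exponent: float = 1.0
    stages_x: float = 1.0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not self.beta > 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if not self.stages_x > 0:
            raise ValueError(f"stages_x must be positive, got {self.stages_x}")
        if self.k is not None and not self.k > 0:
            raise ValueError(f"k must be positive when set, got {self.k}")

    def check_k(self, a_div: float, rtol: float = 1e-9) -> None:
        """Verify ``beta = k * A_div`` at a given division area."""
        if self.k is None:
            return
        expected = self.k * a_div
        if abs(expected - self.beta) > rtol * max(abs(self.beta), 1e-300):
            raise ValueError(
                f"beta = k*A_div violated: beta={self.beta}, k*A_div={expected}"
            )

    def k_at(self, a_div: float) -> float:
        """Specific growth constant implied at division area ``a_div``."""
        if self.k is not None:
            return self.k
        return self.beta / a_div

    def with_alpha(self, alpha: float) -> "GrowthDivisionParams":
        return GrowthDivisionParams(
            alpha=alpha, beta=self.beta, k=self.k,
            size_exponent=self.size_exponent, stages_x=self.stages_x,
        )

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "alpha": self.alpha,
            "beta": self.beta,
            "k": self.k,
            "size_exponent": self.size_exponent,
            "stages_x": self.stages_x,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GrowthDivisionParams":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        doc = json.loads(text)
        allowed = {"alpha", "beta", "k", "size_exponent", "stages_x"}
        unknown = set(doc) - allowed
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**doc)


@dataclass
class SizeMapState:
    """One generation of the iterated division-size map."""

    a_div: float
    t_m: float
    generation_n: int

    def __post_init__(self) -> None:
        if not self.a_div > 0:
            raise ValueError("A_div must be positive")
        if not self.t_m > 0:
            raise ValueError("t_m must be positive")
        if self.generation_n < 0:
            raise ValueError("generation index must be non-negative")


@dataclass(frozen=True)
class RateConstants:
    """Rates of the exponential cycle-time and added-size laws.

    ``lambda_cycle`` is the division-time rate (per step) and
    ``lambda_size`` the added-area rate (per um^2); they satisfy
    ``lambda_size * beta = lambda_cycle``.
    """

    lambda_cycle: float
    lambda_size: float
    beta: float = field(default=float("nan"), compare=False)

    def __post_init__(self) -> None:
        if not self.lambda_cycle > 0 or not self.lambda_size > 0:
            raise ValueError("rates must be strictly positive")
        if self.beta == self.beta:  # beta provided (not NaN)
            if abs(self.lambda_size * self.beta - self.lambda_cycle) > 1e-9 * self.lambda_cycle:
                raise ValueError("lambda_size * beta must equal lambda_cycle")
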