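"""Delimited-text readers and writers for the pipeline's formats.

All artifacts are plain text: abundance matrices as TSV (first column
feature id, header row of line ids), panels as CSV, single-cell area
samples as single-column CSV, growth curves as TSV (time_h, well,
count), distributions as two-column CSV, parameters and run summaries
as JSON.  Numeric values round-trip at full double precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import FitResult, GrowthCurve
from .simulate import AreaDistribution

__all__ = [
    "read_abundance_matrix",
    "write_abundance_matrix",
    "read_panel",
    "write_panel",
    "read_areas",
    "write_areas",
    "read_growth_curve",
    "write_growth_curve",
    "read_distribution",
    "write_distribution",
    "write_fit_result",
    "load_config",
]


def read_abundance_matrix(path: str | Path) -> pd.DataFrame:
    """Read a features x lines TSV matrix.

    Duplicate feature ids are rejected; missing cells are allowed and
    kept as NaN; any other non-numeric cell raises with its location.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature id(s): {dup}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    stripped = df.apply(lambda c: c.str.strip())
    bad = numeric.isna() & stripped.notna() & (stripped != "")
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at feature {df.index[i]!r}, "
            f"line {df.columns[j]!r}: {df.iat[i, j]!r}"
        )
    return numeric


def write_abundance_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="feature",
              float_format="%.17g")


def read_panel(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "line_id" not in df.columns or "mean_area_um2" not in df.columns:
        raise ValueError("panel CSV needs line_id and mean_area_um2 columns")
    return df.set_index("line_id")


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, index_label="line_id", float_format="%.17g")


def read_areas(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, float_precision="round_trip")
    return df.iloc[:, 0].to_numpy(float)


def write_areas(areas: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"area_um2": np.asarray(areas, float)}).to_csv(
        path, index=False, float_format="%.17g")


def read_growth_curve(path: str | Path, mean_area: float) -> GrowthCurve:
    """Read a growth TSV (time_h, well, count) into a GrowthCurve."""
    df = pd.read_csv(path, sep="\t")
    need = {"time_h", "well", "count"}
    if not need.issubset(df.columns):
        raise ValueError(f"growth TSV needs columns {sorted(need)}")
    wide = df.pivot(index="well", columns="time_h", values="count").sort_index()
    return GrowthCurve(
        timepoints=wide.columns.to_numpy(float),
        counts=wide.to_numpy(float),
        mean_area=mean_area,
    )


def write_growth_curve(curve: GrowthCurve, path: str | Path) -> None:
    rows = []
    for w in range(curve.counts.shape[0]):
        for t, c in zip(curve.timepoints, curve.counts[w]):
            rows.append({"time_h": t, "well": w + 1, "count": c})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.17g")


def read_distribution(path: str | Path) -> AreaDistribution:
    return AreaDistribution.from_frame(
        pd.read_csv(path, float_precision="round_trip"))


def write_distribution(dist: AreaDistribution, path: str | Path) -> None:
    dist.to_frame().to_csv(path, index=False, float_format="%.17g")


def write_fit_result(result: FitResult, path: str | Path) -> None:
    doc = {
        "alpha_hat": result.alpha_hat,
        "beta_used": result.beta_used,
        "kl_final": result.kl_final,
        "n_grid_evals": result.n_grid_evals,
        "n_sgd_iters": result.n_sgd_iters,
        "converged": result.converged,
        "on_boundary": result.on_boundary,
        "grid_alphas": result.grid_alphas.tolist(),
        "grid_kl": result.grid_kl.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_config(path: str | Path, allowed_keys: set[str] | None = None) -> dict:
    """Load a YAML or JSON run configuration, rejecting unknown keys."""
    p = Path(path)
    text = p.read_text()
    if p.suffix == ".json":
        doc = json.loads(text)  # YAML 1.1 would read "1e-07" as a string
    else:
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError("config must be a mapping")
    if allowed_keys is not None:
        unknown = set(doc) - allowed_keys
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return doc
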