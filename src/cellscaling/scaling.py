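"""Size-scaling statistics for omics panels.

Abundance matrices (features x cell lines) are normalized to mass
fractions and rescaled so every feature averages 100 units across
lines.  A feature's relation to cell size is summarized by the Pearson
correlation R of its abundance with line mean area and the fold change
Fc between lines above and below the panel mean area; features with
Fc > 1.5 or Fc < 0.66 and |R| > 0.55 are called sub-/super-scaling
hits.  The Fc threshold is the minimal detectable difference of a
two-sample power analysis between the small and large line clusters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "MassFractionScaler",
    "normalize_mass_fraction",
    "size_scaling_stats",
    "call_scaling_hits",
    "min_detectable_fc",
    "adjusted_phospho_abundance",
    "ratio_covariates",
    "mrna_protein_correlations",
    "area_distribution_stats",
    "effect_size_matrix",
]


def _rescale_rows(df: pd.DataFrame, center: float = 100.0) -> pd.DataFrame:
    means = df.mean(axis=1, skipna=True)
    zero = means == 0
    if zero.any():
        dropped = df.index[zero].tolist()
        logger.warning("dropping %d all-zero feature rows: %s",
                       len(dropped), dropped[:5])
        warnings.warn(f"dropped {len(dropped)} all-zero feature rows")
        df = df.loc[~zero]
        means = means.loc[~zero]
    return df.div(means, axis=0) * center


def normalize_mass_fraction(raw: pd.DataFrame, center: float = 100.0) -> pd.DataFrame:
    """Convert raw abundances to scaled mass fractions.

    Step 1 divides each sample column by its column sum so values
    reflect abundance per total signal; step 2 rescales each feature
    row to mean ``center`` (100 scaled units) across lines.  Missing
    values are preserved; row means use observed lines only.
    """
    if (raw.fillna(0) < 0).to_numpy().any():
        raise ValueError("raw abundances must be non-negative")
    colsums = raw.sum(axis=0, skipna=True)
    if (colsums == 0).any():
        bad = colsums.index[colsums == 0].tolist()
        raise ValueError(f"all-zero sample column(s): {bad}")
    fractions = raw.div(colsums, axis=1)
    return _rescale_rows(fractions, center)


class MassFractionScaler(BaseEstimator, TransformerMixin):
    """Transformer wrapper around :func:`normalize_mass_fraction`.

    Operates on DataFrames with features as rows and samples as
    columns; stateless (each matrix is normalized per-sample), so
    ``fit`` only validates.
    """

    def __init__(self, center: float = 100.0):
        self.center = center

    def fit(self, X: pd.DataFrame, y=None):
        self.n_features_in_ = X.shape[0]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return normalize_mass_fraction(X, center=self.center)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3 or np.std(x[mask]) == 0 or np.std(y[mask]) == 0:
        return np.nan, np.nan
    r, p = sps.pearsonr(x[mask], y[mask])
    return float(r), float(p)


def size_scaling_stats(
    matrix: pd.DataFrame,
    panel: pd.DataFrame,
    split_area: float | None = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Per-feature size correlation R and large/small fold change Fc.

    ``panel`` must carry ``line_id`` (or index) and ``mean_area_um2``.
    The fold change splits lines at ``split_area`` (default: the mean
    of the line mean areas) and divides the large-group mean abundance
    by the small-group mean.
    """
    areas = _panel_areas(panel).reindex(matrix.columns)
    if areas.isna().any():
        missing = areas.index[areas.isna()].tolist()
        raise ValueError(f"panel lacks mean areas for lines: {missing}")
    if split_area is None:
        split_area = float(areas.mean())
    large = areas.index[areas > split_area]
    small = areas.index[areas <= split_area]
    if len(large) < 4 or len(small) < 4:
        raise ValueError(
            f"need >= 4 lines per group after the split at {split_area:.0f} "
            f"um^2 (got {len(large)} large, {len(small)} small)"
        )
    area_vec = areas.to_numpy(float)
    values = matrix.to_numpy(float)
    corr = np.empty(matrix.shape[0])
    pval = np.empty(matrix.shape[0])
    for i in range(matrix.shape[0]):
        if method == "spearman":
            row = values[i]
            mask = np.isfinite(row)
            if mask.sum() < 3 or np.std(row[mask]) == 0:
                corr[i], pval[i] = np.nan, np.nan
            else:
                corr[i], pval[i] = sps.spearmanr(area_vec[mask], row[mask])
        else:
            corr[i], pval[i] = _pearson(area_vec, values[i])
    mean_large = matrix[large].mean(axis=1, skipna=True)
    mean_small = matrix[small].mean(axis=1, skipna=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_large / mean_small
    return pd.DataFrame({
        "R": corr, "p": pval, "Fc": fc,
        "n_large": len(large), "n_small": len(small),
    }, index=matrix.index)


def _panel_areas(panel: pd.DataFrame) -> pd.Series:
    if "line_id" in panel.columns:
        return panel.set_index("line_id")["mean_area_um2"].astype(float)
    return panel["mean_area_um2"].astype(float)


def call_scaling_hits(
    stats: pd.DataFrame,
    fc_hi: float = 1.5,
    fc_lo: float = 0.66,
    r_abs: float = 0.55,
) -> pd.DataFrame:
    """Strict-threshold hit calling on the (R, Fc) table.

    A feature is a hit iff (Fc > fc_hi or Fc < fc_lo) and |R| > r_abs
    (all inequalities strict).  Direction is ``super`` for Fc > 1 and
    ``sub`` otherwise.  A Benjamini-Hochberg column is included for
    transparency but never gates hits.
    """
    if not (fc_lo < 1.0 < fc_hi) or fc_lo <= 0:
        raise ValueError("require 0 < fc_lo < 1 < fc_hi")
    out = stats.copy()
    fc = out["Fc"]
    r = out["R"]
    out["hit"] = ((fc > fc_hi) | (fc < fc_lo)) & (r.abs() > r_abs)
    out["hit"] &= fc.notna() & r.notna()
    out["direction"] = np.where(fc > 1.0, "super", "sub")
    out.loc[fc.isna(), "direction"] = ""
    finite_p = out["p"].fillna(1.0).to_numpy()
    out["p_bh"] = multipletests(finite_p, method="fdr_bh")[1]
    out.loc[out["p"].isna(), "p_bh"] = np.nan
    return out


def min_detectable_fc(
    n1: int = 5,
    n2: int = 6,
    sd: float = 20.0,
    power: float = 0.95,
    center: float = 100.0,
    alpha: float = 0.05,
    two_sided: bool = False,
) -> float:
    """Minimal detectable fold change of a two-sample comparison.

    A normal-approximation power analysis gives the smallest detectable
    mean difference ``d = (z_{1-a} + z_{power}) * sd * sqrt(1/n1+1/n2)``
    (one-sided at alpha = 0.05 by default).  With the two group means
    constrained to average ``center`` (every feature is scaled to mean
    100), the fold change is ``(center + d/2) / (center - d/2)``.
    """
    if min(n1, n2) <= 0 or sd <= 0 or center <= 0:
        raise ValueError("n1, n2, sd, center must be positive")
    if not 0 < power < 1:
        raise ValueError("power must be in (0,1)")
    tail = alpha / 2.0 if two_sided else alpha
    z = sps.norm.ppf(1.0 - tail) + sps.norm.ppf(power)
    d = z * sd * np.sqrt(1.0 / n1 + 1.0 / n2)
    if d >= 2.0 * center:
        raise ValueError("detectable difference exceeds twice the center; Fc undefined")
    return float((center + d / 2.0) / (center - d / 2.0))


def adjusted_phospho_abundance(
    phospho: pd.DataFrame,
    peptides: pd.DataFrame,
    parent_map: pd.Series,
    center: float = 100.0,
) -> pd.DataFrame:
    """Phosphopeptide abundance relative to its parent peptide.

    ``parent_map`` maps each phosphopeptide id to a parent peptide id
    present in ``peptides``.  Adjusted values are the per-line ratio
    phospho/parent, row-rescaled to mean ``center``; cells with a zero
    parent abundance become missing (logged).
    """
    missing = [i for i in phospho.index if i not in parent_map.index]
    if missing:
        raise ValueError(f"phosphopeptides without parent mapping: {missing[:5]}")
    absent = [p for p in parent_map.loc[phospho.index] if p not in peptides.index]
    if absent:
        raise ValueError(f"parent peptides absent from peptide matrix: {absent[:5]}")
    parents = peptides.loc[parent_map.loc[phospho.index]]
    parents.index = phospho.index
    parent_vals = parents.to_numpy(float)
    zero = parent_vals == 0
    if zero.any():
        logger.warning("parent abundance 0 in %d cells; emitted as missing",
                       int(zero.sum()))
        parent_vals = np.where(zero, np.nan, parent_vals)
    ratio = pd.DataFrame(phospho.to_numpy(float) / parent_vals,
                         index=phospho.index, columns=phospho.columns)
    return _rescale_rows(ratio, center)


def ratio_covariates(
    matrix: pd.DataFrame,
    numerator_features: list,
    denominator_features: list,
    fc_hi: float = 1.5,
    fc_lo: float = 0.66,
    r_abs: float = 0.55,
) -> pd.DataFrame:
    """Correlate every feature with a per-line feature-set ratio.

    The ratio per line is mean(numerator features)/mean(denominator
    features).  Fc is computed across ratio-above/below-median halves;
    hits use the standard thresholds.
    """
    if not numerator_features or not denominator_features:
        raise ValueError("both feature sets must be non-empty")
    num = matrix.loc[numerator_features].mean(axis=0, skipna=True)
    den = matrix.loc[denominator_features].mean(axis=0, skipna=True)
    if (den == 0).any():
        raise ValueError("denominator feature-set mean is zero for some line")
    ratio = num / den
    values = matrix.to_numpy(float)
    rvec = ratio.to_numpy(float)
    corr = np.empty(matrix.shape[0])
    pval = np.empty(matrix.shape[0])
    for i in range(matrix.shape[0]):
        corr[i], pval[i] = _pearson(rvec, values[i])
    median = float(np.median(rvec))
    hi_lines = ratio.index[rvec > median]
    lo_lines = ratio.index[rvec <= median]
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = matrix[hi_lines].mean(axis=1) / matrix[lo_lines].mean(axis=1)
    stats_df = pd.DataFrame({
        "R": corr, "p": pval, "Fc": fc,
        "n_large": len(hi_lines), "n_small": len(lo_lines),
    }, index=matrix.index)
    out = call_scaling_hits(stats_df, fc_hi=fc_hi, fc_lo=fc_lo, r_abs=r_abs)
    out.insert(0, "ratio_median", median)
    return out


# significance presets: |R| thresholds by subset (sample size across lines)
MRNA_R_THRESHOLDS = {"all": 0.55, "small": 0.70, "large": 0.75}


def mrna_protein_correlations(
    rna: pd.DataFrame,
    protein: pd.DataFrame,
    panel: pd.DataFrame,
    mode: str = "per_gene",
    subset: str = "all",
    split_area: float | None = None,
    r_threshold: float | None = None,
) -> pd.DataFrame:
    """Pearson correlation of mRNA and protein abundance.

    ``per_line`` gives one coefficient per cell line across genes on
    log10 abundances; ``per_gene`` gives one coefficient per gene
    across the lines of ``subset`` ('all', 'small', 'large'; split at
    the panel mean area) on linear scaled units.  Significance flags
    require |R| above the subset preset (0.55/0.70/0.75) and p < 0.05.
    """
    genes = rna.index.intersection(protein.index)
    if genes.empty:
        raise ValueError("no shared gene ids between matrices")
    rna = rna.loc[genes]
    protein = protein.loc[genes]
    areas = _panel_areas(panel).reindex(rna.columns)
    if split_area is None:
        split_area = float(areas.mean())
    if subset == "all":
        lines = list(rna.columns)
    elif subset == "small":
        lines = [c for c in rna.columns if areas[c] <= split_area]
    elif subset == "large":
        lines = [c for c in rna.columns if areas[c] > split_area]
    else:
        raise ValueError(f"unknown subset {subset!r}")
    if len(lines) < 3:
        raise ValueError(f"fewer than 3 lines in subset {subset!r}")
    if r_threshold is None:
        r_threshold = MRNA_R_THRESHOLDS[subset]

    if mode == "per_line":
        rows = []
        for line in lines:
            x = np.log10(rna[line].to_numpy(float))
            y = np.log10(protein[line].to_numpy(float))
            ok = np.isfinite(x) & np.isfinite(y)
            r, p = _pearson(x[ok], y[ok])
            rows.append({"line_id": line, "R": r, "p": p, "n_genes": int(ok.sum())})
        out = pd.DataFrame(rows).set_index("line_id")
    elif mode == "per_gene":
        x = rna[lines].to_numpy(float)
        y = protein[lines].to_numpy(float)
        corr = np.empty(len(genes))
        pval = np.empty(len(genes))
        for i in range(len(genes)):
            corr[i], pval[i] = _pearson(x[i], y[i])
        out = pd.DataFrame({"R": corr, "p": pval, "n_lines": len(lines)},
                           index=genes)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out["significant"] = (out["R"].abs() > r_threshold) & (out["p"] < 0.05)
    return out


def area_distribution_stats(
    areas_by_line: dict[str, np.ndarray],
    min_cells: int = 100,
) -> tuple[pd.DataFrame, dict[str, np.ndarray], dict[str, float]]:
    """Per-line moments plus acosh-transformed test battery.

    Raw moments (mean, variance, CV, skew) are computed on untransformed
    areas; the acosh transform (defined for areas >= 1 um^2) is applied
    before the normality (Shapiro-Wilk per line), equal-variance
    (Bartlett) and k-way location (one-way ANOVA) tests.  Flags are
    reported without interpretation.
    """
    rows = []
    transformed: dict[str, np.ndarray] = {}
    for line, arr in areas_by_line.items():
        arr = np.asarray(arr, dtype=float)
        if arr.size < min_cells:
            raise ValueError(f"line {line!r}: need >= {min_cells} cells, got {arr.size}")
        if np.any(arr < 1.0):
            idx = int(np.argmax(arr < 1.0))
            raise ValueError(
                f"line {line!r}, record {idx}: area {arr[idx]} < 1 um^2 "
                "is outside the acosh domain"
            )
        var = float(np.var(arr, ddof=1))
        mean = float(np.mean(arr))
        skew = float(sps.skew(arr)) if var > 0 else np.nan
        cv = float(np.sqrt(var) / mean) if mean > 0 else np.nan
        transformed[line] = np.arccosh(arr)
        sample = transformed[line]
        if sample.size > 4000:  # Shapiro-Wilk accuracy degrades at large n
            sample = sample[:: sample.size // 4000 + 1]
        sw_p = float(sps.shapiro(sample).pvalue) if var > 0 else np.nan
        rows.append({
            "line_id": line, "mean": mean,
            "variance": var if var > 0 else 0.0,
            "cv": cv if var > 0 else 0.0,
            "skew": skew, "shapiro_p": sw_p, "n": arr.size,
        })
    summary = pd.DataFrame(rows).set_index("line_id")
    flags: dict[str, float] = {}
    if len(transformed) >= 2:
        groups = list(transformed.values())
        flags["bartlett_p"] = float(sps.bartlett(*groups).pvalue)
        flags["anova_p"] = float(sps.f_oneway(*groups).pvalue)
    return summary, transformed, flags


def _common_language(a: np.ndarray, b: np.ndarray) -> float:
    """P(random member of a exceeds random member of b), ties count 1/2."""
    u = sps.mannwhitneyu(a, b, alternative="two-sided").statistic
    return float(u) / (len(a) * len(b))


@dataclass
class SizeClassResult:
    cl_matrix: pd.DataFrame
    classes: pd.Series  # 1..n_classes ordered by class mean area


def effect_size_matrix(
    areas_by_line: dict[str, np.ndarray],
    n_classes: int = 3,
) -> SizeClassResult:
    """Pairwise common-language effect sizes and a size-class partition.

    Entry (i, j) is the probability that a random cell of line i is
    larger than a random cell of line j (rank-sum U / (n_i * n_j), ties
    half-counted); the diagonal is 0.5.  Lines are clustered by average
    linkage on the |CL - 0.5| distance and cut into ``n_classes``
    classes ordered by class mean area (class 1 = smallest).
    """
    lines = list(areas_by_line)
    if len(lines) == 1:
        mat = pd.DataFrame([[0.5]], index=lines, columns=lines)
        return SizeClassResult(mat, pd.Series([1], index=lines, name="size_class"))
    n = len(lines)
    cl = np.full((n, n), 0.5)
    for i in range(n):
        for j in range(i + 1, n):
            v = _common_language(np.asarray(areas_by_line[lines[i]], float),
                                 np.asarray(areas_by_line[lines[j]], float))
            cl[i, j] = v
            cl[j, i] = 1.0 - v
    mat = pd.DataFrame(cl, index=lines, columns=lines)
    dist = np.abs(cl - 0.5)
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    k = min(n_classes, n)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    means = {line: float(np.mean(areas_by_line[line])) for line in lines}
    class_means = {}
    for lab in np.unique(labels):
        members = [lines[i] for i in range(n) if labels[i] == lab]
        class_means[lab] = np.mean([means[m] for m in members])
    order = {lab: rank + 1 for rank, lab in
             enumerate(sorted(class_means, key=class_means.get))}
    classes = pd.Series([order[l] for l in labels], index=lines, name="size_class")
    return SizeClassResult(mat, classes)
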