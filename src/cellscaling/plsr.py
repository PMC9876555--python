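"""Partial least-squares regression with signed VIP scores.

PLSR predicts model parameters (or growth rate) from abundance
matrices while tolerating the strong collinearity of omics predictors.
Components are selected by five-fold cross-validation on the mean
squared error.  Per-predictor influence is summarized by the variable
importance in projection

    VIP_j = sqrt( sum_f  w_jf^2 * SSY_f * J / (SSY_total * F) )

with ``w_jf`` the unit-norm predictor weights, ``SSY_f`` the response
variance explained by component ``f``, ``SSY_total`` their sum, ``J``
the predictor count and ``F`` the component count.  Scores inherit a
negative sign when the predictor's first-component weight is negative,
so ranked exports distinguish positively and negatively driving
features; |VIP| > 1 flags major drivers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PLSRegressionVIP",
    "VIPResult",
    "fit_plsr",
    "select_components_cv",
    "vip_scores",
    "ranked_export",
]


@dataclass
class VIPResult:
    """Signed per-predictor VIP scores and their rank order."""

    signed_vip: np.ndarray
    rank_order: np.ndarray  # permutation: indices sorted by signed VIP desc

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.signed_vip)):
            raise ValueError("VIP scores must be finite")
        if sorted(self.rank_order.tolist()) != list(range(self.signed_vip.size)):
            raise ValueError("rank_order must be a permutation")


class PLSRegressionVIP(BaseEstimator, RegressorMixin):
    """PLS2 regression exposing weights, explained variance and VIP.

    Parameters
    ----------
    n_components : int
        Number of latent components F.
    vip_mode : {'printed', 'classical'}
        'printed' includes the 1/F factor inside the square root;
        'classical' omits it (the textbook definition).
    scale : bool
        Autoscale predictors to unit variance (centering always on).

    Fitted attributes: ``weights_`` (J x F, unit-norm columns),
    ``ssy_f_``, ``ssy_total_``, ``vip_``, ``signed_vip_``, ``r2_``.
    """

    def __init__(self, n_components: int = 2, vip_mode: str = "printed",
                 scale: bool = False):
        self.n_components = n_components
        self.vip_mode = vip_mode
        self.scale = scale

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if self.vip_mode not in ("printed", "classical"):
            raise ValueError(f"unknown vip_mode {self.vip_mode!r}")
        rank = np.linalg.matrix_rank(X - X.mean(axis=0))
        if self.n_components > rank:
            raise ValueError(
                f"n_components={self.n_components} exceeds rank(X)={rank}"
            )
        pls = PLSRegression(n_components=self.n_components, scale=self.scale)
        pls.fit(X, Y)
        self.pls_ = pls
        W = pls.x_weights_  # columns unit-norm
        T = pls.x_scores_
        Q = pls.y_loadings_
        # response variance explained by component f on training data:
        # deflation makes scores orthogonal, so SSY_f = ||t_f q_f^T||^2
        ssy = np.array([
            float(T[:, f] @ T[:, f]) * float(Q[:, f] @ Q[:, f])
            for f in range(self.n_components)
        ])
        self.weights_ = W
        self.scores_ = T
        self.loadings_ = pls.x_loadings_
        self.y_loadings_ = Q
        self.ssy_f_ = ssy
        self.ssy_total_ = float(ssy.sum())
        if self.ssy_total_ == 0:
            raise ValueError("model explains no response variance; VIP undefined")
        J, F = W.shape
        denom = self.ssy_total_ * (F if self.vip_mode == "printed" else 1.0)
        vip = np.sqrt((W ** 2 @ ssy) * J / denom)
        self.vip_ = vip
        sign = np.where(W[:, 0] < 0, -1.0, 1.0)
        self.signed_vip_ = vip * sign
        Yc = Y - Y.mean(axis=0)
        resid = Y - pls.predict(X)
        self.r2_ = 1.0 - float((resid ** 2).sum()) / float((Yc ** 2).sum())
        self.n_features_in_ = J
        return self

    def predict(self, X):
        check_is_fitted(self, "pls_")
        return self.pls_.predict(X)

    def vip_result(self) -> VIPResult:
        check_is_fitted(self, "signed_vip_")
        order = np.argsort(-self.signed_vip_, kind="stable")
        return VIPResult(signed_vip=self.signed_vip_.copy(), rank_order=order)


def fit_plsr(X, Y, n_components: int, vip_mode: str = "printed") -> PLSRegressionVIP:
    """Fit a PLS2 model; thin functional wrapper over the estimator."""
    return PLSRegressionVIP(n_components=n_components, vip_mode=vip_mode).fit(X, Y)


def select_components_cv(
    X,
    Y,
    folds: int = 5,
    max_components: int | None = None,
    rng_seed: int = 0,
    selection: str = "one_se",
) -> tuple[int, np.ndarray]:
    """Choose the component count from the cross-validated MSE curve.

    ``selection='one_se'`` (default) applies the elbow/parsimony rule:
    the smallest component count whose mean CV MSE lies within one
    standard error of the curve minimum — on noise-dominated responses
    this collapses to the one-component model.  ``'strict_min'`` takes
    the literal argmin.  Returns ``(F, cv_curve)``; fold assignment is
    seeded and shuffled.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if n < folds:
        raise ValueError(f"need at least {folds} samples, got {n}")
    if max_components is None:
        max_components = min(10, n - int(np.ceil(n / folds)) - 1, X.shape[1])
    max_components = max(1, max_components)
    kf = KFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    curve = np.zeros(max_components)
    se = np.zeros(max_components)
    for f in range(1, max_components + 1):
        errs = []
        for tr, te in kf.split(X):
            pls = PLSRegression(n_components=min(f, len(tr) - 1), scale=False)
            pls.fit(X[tr], Y[tr])
            pred = pls.predict(X[te])
            errs.append(float(((Y[te] - pred) ** 2).mean()))
        curve[f - 1] = float(np.mean(errs))
        se[f - 1] = float(np.std(errs) / np.sqrt(len(errs)))
    i_min = int(np.argmin(curve))
    if selection == "strict_min":
        return i_min + 1, curve
    if selection != "one_se":
        raise ValueError(f"unknown selection {selection!r}")
    threshold = curve[i_min] + se[i_min]
    return int(np.argmax(curve <= threshold)) + 1, curve


def vip_scores(model: PLSRegressionVIP) -> VIPResult:
    """Signed VIP scores of a fitted model."""
    return model.vip_result()


def ranked_export(
    vip: VIPResult,
    feature_ids: list[str],
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Two-column table of features sorted by signed VIP, descending.

    Ties break lexicographically by feature id so exports are stable
    across runs; written tab-separated for external enrichment tools.
    """
    ids = list(feature_ids)
    if len(ids) != vip.signed_vip.size:
        raise ValueError("feature_ids length does not match VIP scores")
    df = pd.DataFrame({"feature": ids, "score": vip.signed_vip})
    df = df.sort_values(["score", "feature"],
                        ascending=[False, True], kind="stable")
    df = df.reset_index(drop=True)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
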