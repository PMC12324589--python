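"""Single-response partial least squares (NIPALS PLS1) with a transferable
rotation.

The engine fits latent components that maximize covariance between a
standardized feature matrix X and a -1/+1 trait code y, extracting components
sequentially with X-deflation so each new component is orthogonal to the
previous ones.  Besides weights W, loadings P and scores T it exposes the
rotation R = W (P'W)^-1, the linear map from standardized features to scores
that makes out-of-sample (and cross-cohort, block-restricted) projection a
single matrix product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FeatureMatrix, TraitVector

__all__ = ["PlsModel", "ModeScoreSet", "fit_pls", "latent_correlation", "transform", "align_signs"]


@dataclass
class PlsModel:
    """Fitted PLS1 model; all matrices are feature x component."""

    x_weights: np.ndarray  # W, p x K, unit-norm columns
    x_loadings: np.ndarray  # P, p x K
    y_loadings: np.ndarray  # c, K
    x_scores: np.ndarray  # T, n x K
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    rotation: np.ndarray  # R = W (P'W)^-1, p x K
    feature_names: list
    block_labels: np.ndarray
    scale: bool

    @property
    def n_components(self) -> int:
        return self.x_weights.shape[1]

    @property
    def n_features(self) -> int:
        return self.x_weights.shape[0]


@dataclass
class ModeScoreSet:
    """Per-participant expression of each latent mode ("brain scores")."""

    scores: pd.DataFrame  # columns comp1..compK
    trait_correlation: np.ndarray | None = None  # r_k vs the trait, if computed

    @property
    def values(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    @property
    def component_index(self) -> list:
        return list(range(1, self.scores.shape[1] + 1))


def _standardize(x: np.ndarray, scale: bool):
    mean = x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
    else:
        sd = np.ones(x.shape[-1] if x.ndim > 1 else 1)
    return (x - mean) / sd, mean, sd


def nipals_pls1(x0: np.ndarray, y0: np.ndarray, n_components: int):
    """NIPALS PLS1 on pre-centered arrays; returns (W, P, c, T).

    Deflates X only: for a single response, y-deflation changes nothing
    because deflated X columns are orthogonal to earlier scores.  Stops early
    (with a warning) when X is exhausted.
    """
    n, p = x0.shape
    k_max = min(n_components, n - 1, p)
    xk = x0.copy()
    ws, ps, cs, ts = [], [], [], []
    eps = np.finfo(float).eps
    x_norm0 = np.linalg.norm(x0)
    for _ in range(k_max):
        w = xk.T @ y0
        w_norm = np.linalg.norm(w)
        if w_norm <= eps * max(1.0, x_norm0):
            break
        w /= w_norm
        t = xk @ w
        tt = t @ t
        if tt <= eps * max(1.0, x_norm0**2):
            break
        pvec = xk.T @ t / tt
        c = y0 @ t / tt
        xk -= np.outer(t, pvec)
        ws.append(w)
        ps.append(pvec)
        cs.append(c)
        ts.append(t)
    if not ws:
        raise ValueError("X carries no covariance with y (all-zero weights)")
    if len(ws) < n_components:
        warnings.warn(
            f"rank exhausted: fitted {len(ws)} of {n_components} requested "
            "components",
            stacklevel=3,
        )
    w_mat = np.column_stack(ws)
    p_mat = np.column_stack(ps)
    return w_mat, p_mat, np.array(cs), np.column_stack(ts)


def _as_xy(x, y):
    if isinstance(x, FeatureMatrix):
        names, labels, vals = x.feature_names, x.block_labels, x.values
    else:
        vals = np.asarray(x, dtype=float)
        names = [f"f{i}" for i in range(vals.shape[1])]
        labels = np.array(["generic"] * vals.shape[1], dtype=object)
    yv = y.values if isinstance(y, TraitVector) else np.asarray(y, dtype=float)
    return vals, yv, names, labels


def fit_pls(
    x,
    y,
    n_components: int = 10,
    scale: bool = True,
) -> PlsModel:
    """Fit NIPALS PLS1 of the feature matrix on the -1/+1 trait.

    Features are centered and (by default) unit-variance scaled inside the
    fit; the centering parameters are stored on the model so new cohorts can
    be projected.  Deterministic — no randomness is involved.
    """
    vals, yv, names, labels = _as_xy(x, y)
    if np.isnan(vals).any():
        raise ValueError("feature matrix contains NaNs; prep must drop them")
    if np.isnan(yv).any():
        raise ValueError("trait contains missing values; drop them before fitting")
    if vals.shape[0] != yv.shape[0]:
        raise ValueError("X and y row counts differ")
    if np.ptp(yv) == 0:
        raise ValueError("degenerate target: y is constant")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if vals.shape[0] <= n_components:
        raise ValueError("need n > n_components participants")

    x0, x_mean, x_scale = _standardize(vals, scale)
    y_mean = float(yv.mean())
    y_scale = float(yv.std(ddof=1)) if scale else 1.0
    y0 = (yv - y_mean) / y_scale

    w_mat, p_mat, c_vec, t_mat = nipals_pls1(x0, y0, n_components)
    rot = w_mat @ np.linalg.inv(p_mat.T @ w_mat)
    return PlsModel(
        x_weights=w_mat,
        x_loadings=p_mat,
        y_loadings=c_vec,
        x_scores=t_mat,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        rotation=rot,
        feature_names=list(names),
        block_labels=np.asarray(labels, dtype=object),
        scale=scale,
    )


def latent_correlation(model: PlsModel, y) -> pd.DataFrame:
    """Pearson r (and two-sided p, t transform with n-2 df) of each
    component's x-scores with the trait."""
    yv = y.values if isinstance(y, TraitVector) else np.asarray(y, dtype=float)
    t_mat = model.x_scores
    if t_mat.shape[0] != yv.shape[0]:
        raise ValueError("scores and trait are not aligned")
    if t_mat.shape[0] < 3:
        raise ValueError("need at least 3 participants for a correlation test")
    rows = []
    for k in range(model.n_components):
        r, p = stats.pearsonr(t_mat[:, k], yv)
        rows.append({"component": k + 1, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows).set_index("component")


def score_trait_correlations(t_mat: np.ndarray, yv: np.ndarray) -> np.ndarray:
    """Vectorized Pearson r of each score column with y (no p-values)."""
    tc = t_mat - t_mat.mean(0)
    yc = yv - yv.mean()
    denom = np.sqrt((tc**2).sum(0) * (yc @ yc))
    return (tc.T @ yc) / denom


def transform(model: PlsModel, x_new) -> ModeScoreSet:
    """Project new participants into the model's latent space.

    Columns are matched to the training features by *name* (reordering is
    fine; missing or extra features are an error); scores are
    ((X - x_mean) / x_scale) @ R.
    """
    if isinstance(x_new, FeatureMatrix):
        missing = [f for f in model.feature_names if f not in x_new.data.columns]
        extra = [f for f in x_new.feature_names if f not in set(model.feature_names)]
        if missing or extra:
            raise ValueError(
                f"feature mismatch: missing {missing[:5]} extra {extra[:5]}"
            )
        vals = x_new.data.loc[:, model.feature_names].to_numpy(dtype=float)
        index = x_new.participant_ids
    else:
        vals = np.asarray(x_new, dtype=float)
        if vals.shape[1] != model.n_features:
            raise ValueError(
                f"expected {model.n_features} features, got {vals.shape[1]}"
            )
        index = pd.RangeIndex(vals.shape[0])
    scores = ((vals - model.x_mean) / model.x_scale) @ model.rotation
    frame = pd.DataFrame(
        scores, index=index, columns=[f"comp{k+1}" for k in range(model.n_components)]
    )
    return ModeScoreSet(frame)


def align_signs(model: PlsModel, convention: str = "trait-positive", y=None) -> PlsModel:
    """Resolve the arbitrary per-component sign.

    ``trait-positive`` flips each component so its score-trait correlation is
    >= 0 (requires y); ``loading-max-positive`` makes the largest-magnitude
    x-loading positive.  W, P, c, T and R flip jointly, so reconstructions
    and correlation magnitudes are untouched; applying twice is a no-op.
    """
    if convention == "trait-positive":
        if y is None:
            raise ValueError("trait-positive convention needs y")
        yv = y.values if isinstance(y, TraitVector) else np.asarray(y, dtype=float)
        r = score_trait_correlations(model.x_scores, yv)
        signs = np.where(r < 0, -1.0, 1.0)
    elif convention == "loading-max-positive":
        p_mat = model.x_loadings
        top = p_mat[np.abs(p_mat).argmax(axis=0), np.arange(p_mat.shape[1])]
        signs = np.where(top < 0, -1.0, 1.0)
    else:
        raise ValueError(f"unknown sign convention {convention!r}")
    w = model.x_weights * signs
    p = model.x_loadings * signs
    return replace(
        model,
        x_weights=w,
        x_loadings=p,
        y_loadings=model.y_loadings * signs,
        x_scores=model.x_scores * signs,
        rotation=w @ np.linalg.inv(p.T @ w),
    )
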