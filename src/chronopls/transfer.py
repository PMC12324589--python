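"""Block-restricted cross-cohort projection into a trained latent space.

A model trained on the full multimodal feature set can be carried to a cohort
that shares only one block (e.g. gray-matter volumes): the weight and loading
rows for the shared features are extracted and the rotation is *recomputed*
from the restricted matrices, R_sub = W_sub (P_sub' W_sub)^-1, so target
scores are X_sub_std @ R_sub.  Slicing the parent rotation instead would
apply the wrong inverse and is deliberately not offered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureMatrix
from .pls import ModeScoreSet, PlsModel

__all__ = ["RestrictedModel", "restrict_model", "project_cohort"]

_COND_LIMIT = 1e8


@dataclass
class RestrictedModel:
    kept_features: list
    x_weights: np.ndarray  # p_sub x K
    x_loadings: np.ndarray  # p_sub x K
    rotation: np.ndarray  # p_sub x K, recomputed from the restricted W, P
    x_mean: np.ndarray
    x_scale: np.ndarray
    scale: bool
    condition_number: float

    @property
    def n_components(self) -> int:
        return self.x_weights.shape[1]


def restrict_model(model: PlsModel, block) -> RestrictedModel:
    """Restrict a fitted model to one block (by label) or a feature list."""
    if isinstance(block, str):
        mask = model.block_labels == block
        if not mask.any():
            raise KeyError(
                f"unknown block {block!r}; have {sorted(set(model.block_labels))}"
            )
    else:
        wanted = list(block)
        if not wanted:
            raise ValueError("empty feature list")
        missing = [f for f in wanted if f not in set(model.feature_names)]
        if missing:
            raise KeyError(f"features not in model: {missing[:5]}")
        wanted_set = set(wanted)
        mask = np.array([f in wanted_set for f in model.feature_names])
    kept = [f for f, m in zip(model.feature_names, mask) if m]

    w_sub = model.x_weights[mask]
    p_sub = model.x_loadings[mask]
    gram = p_sub.T @ w_sub
    cond = float(np.linalg.cond(gram))
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise np.linalg.LinAlgError(
            f"P_sub'W_sub is singular or ill-conditioned (cond={cond:.3g}); "
            "use fewer components or a larger feature block"
        )
    rotation = w_sub @ np.linalg.inv(gram)
    return RestrictedModel(
        kept_features=kept,
        x_weights=w_sub,
        x_loadings=p_sub,
        rotation=rotation,
        x_mean=model.x_mean[mask],
        x_scale=model.x_scale[mask],
        scale=model.scale,
        condition_number=cond,
    )


def project_cohort(
    rmodel: RestrictedModel,
    x_target,
    centering: str = "target",
) -> ModeScoreSet:
    """Project a target cohort through the restricted rotation.

    ``centering`` picks the standardization applied before the product:
    ``"target"`` (default) recomputes mean/scale on the target cohort —
    appropriate when source and target measurements are on incomparable raw
    scales; ``"source"`` reuses the training parameters (strict formula
    replication); ``"none"`` applies the rotation to the raw values.
    """
    if isinstance(x_target, FeatureMatrix):
        missing = [f for f in rmodel.kept_features if f not in x_target.data.columns]
        extra = [
            f for f in x_target.feature_names if f not in set(rmodel.kept_features)
        ]
        if missing or extra:
            raise ValueError(
                f"feature mismatch: missing {missing[:5]} extra {extra[:5]}"
            )
        vals = x_target.data.loc[:, rmodel.kept_features].to_numpy(dtype=float)
        index = x_target.participant_ids
    else:
        vals = np.asarray(x_target, dtype=float)
        if vals.shape[1] != len(rmodel.kept_features):
            raise ValueError(
                f"expected {len(rmodel.kept_features)} features, got {vals.shape[1]}"
            )
        index = pd.RangeIndex(vals.shape[0])

    if centering == "source":
        std = (vals - rmodel.x_mean) / rmodel.x_scale
    elif centering == "target":
        if vals.shape[0] == 0:
            std = vals
        else:
            mean = vals.mean(0)
            if rmodel.scale and vals.shape[0] > 1:
                sd = vals.std(0, ddof=1)
                sd = np.where(sd > 0, sd, 1.0)
            else:
                sd = 1.0
            std = (vals - mean) / sd
    elif centering == "none":
        std = vals
    else:
        raise ValueError(f"unknown centering mode {centering!r}")

    scores = std @ rmodel.rotation
    frame = pd.DataFrame(
        scores,
        index=index,
        columns=[f"comp{k+1}" for k in range(rmodel.n_components)],
    )
    return ModeScoreSet(frame)
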