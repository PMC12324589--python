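"""Delimited-table and model (de)serialization.

Tables are TSV/CSV (sep inferred from the extension), header row required,
``participant_id`` as the join key, with ``#``-prefixed provenance comment
lines (package version, seed, config hash) above the header.  Models are a
single JSON document — small enough at desk scale that text arrays beat a
binary sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FeatureMatrix
from .pls import PlsModel

__all__ = [
    "read_table",
    "write_table",
    "read_feature_matrix",
    "write_feature_matrix",
    "save_model",
    "load_model",
]


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def write_table(
    frame: pd.DataFrame,
    path,
    provenance: dict | None = None,
    index: bool = True,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        frame.to_csv(fh, sep=_sep(path), index=index)


def read_table(path, index_col="participant_id") -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep(path), comment="#")
    if index_col is not None and index_col in frame.columns:
        frame = frame.set_index(index_col)
    return frame


def write_feature_matrix(x: FeatureMatrix, path, provenance: dict | None = None) -> None:
    write_table(x.data, path, provenance=provenance)


def read_feature_matrix(path, block_labels=None) -> FeatureMatrix:
    """Read a feature table; block labels default to the ``<BLOCK>_`` prefix
    of each column name."""
    frame = read_table(path)
    return FeatureMatrix(frame.astype(float), block_labels)


def save_model(model: PlsModel, path, provenance: dict | None = None) -> None:
    doc = {
        "format": "chronopls-pls-model",
        "version": 1,
        "provenance": provenance or {},
        "scale": bool(model.scale),
        "feature_names": list(model.feature_names),
        "block_labels": [str(b) for b in model.block_labels],
        "x_weights": model.x_weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "x_scores": model.x_scores.tolist(),
        "x_mean": model.x_mean.tolist(),
        "x_scale": model.x_scale.tolist(),
        "y_mean": model.y_mean,
        "y_scale": model.y_scale,
        "rotation": model.rotation.tolist(),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc))


def load_model(path) -> PlsModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "chronopls-pls-model":
        raise ValueError(f"{path} is not a chronopls model file")
    return PlsModel(
        x_weights=np.array(doc["x_weights"], dtype=float),
        x_loadings=np.array(doc["x_loadings"], dtype=float),
        y_loadings=np.array(doc["y_loadings"], dtype=float),
        x_scores=np.array(doc["x_scores"], dtype=float),
        x_mean=np.array(doc["x_mean"], dtype=float),
        x_scale=np.array(doc["x_scale"], dtype=float),
        y_mean=float(doc["y_mean"]),
        y_scale=float(doc["y_scale"]),
        rotation=np.array(doc["rotation"], dtype=float),
        feature_names=list(doc["feature_names"]),
        block_labels=np.array(doc["block_labels"], dtype=object),
        scale=bool(doc["scale"]),
    )
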