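"""Core in-memory containers shared across the pipeline.

Feature matrices are thin wrappers around a participant-indexed
:class:`pandas.DataFrame` plus a per-column block label (GMV / FA / FC by
default), because block identity — not column position — is what cross-cohort
restriction keys on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "TraitVector",
    "PhenomeMatrix",
    "block_labels_from_names",
]

DEFAULT_BLOCKS = ("GMV", "FA", "FC")


def block_labels_from_names(names) -> np.ndarray:
    """Derive block labels from feature names of the form ``<BLOCK>_<token>``."""
    return np.array([str(n).split("_", 1)[0] for n in names], dtype=object)


@dataclass
class FeatureMatrix:
    """Participants x brain features with named blocks (the PLS X side).

    Parameters
    ----------
    data
        Numeric frame, index = participant_id, columns = unique feature names.
    block_labels
        One label per column (e.g. ``"GMV"``). If omitted, derived from the
        feature-name prefix before the first underscore.
    """

    data: pd.DataFrame
    block_labels: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.block_labels is None:
            self.block_labels = block_labels_from_names(self.data.columns)
        self.block_labels = np.asarray(self.block_labels, dtype=object)
        if len(self.block_labels) != self.data.shape[1]:
            raise ValueError(
                f"block_labels length {len(self.block_labels)} != "
                f"{self.data.shape[1]} feature columns"
            )
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dupes[:5]}")

    # -- basic views -------------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def feature_names(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def participant_ids(self) -> pd.Index:
        return self.data.index

    @property
    def n_participants(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def blocks(self) -> dict[str, list[str]]:
        """Mapping block label -> ordered feature names in that block."""
        out: dict[str, list[str]] = {}
        for name, lab in zip(self.data.columns, self.block_labels):
            out.setdefault(str(lab), []).append(str(name))
        return out

    def block(self, name: str) -> "FeatureMatrix":
        """Restrict to the columns of one block (column order preserved)."""
        mask = self.block_labels == name
        if not mask.any():
            raise KeyError(
                f"unknown block {name!r}; available: {sorted(set(self.block_labels))}"
            )
        return FeatureMatrix(self.data.loc[:, mask], self.block_labels[mask])

    def select_rows(self, ids) -> "FeatureMatrix":
        return FeatureMatrix(self.data.loc[ids], self.block_labels.copy())


@dataclass
class TraitVector:
    """Dichotomized trait coded -1/+1 with NaN for missing (the PLS y side)."""

    code: pd.Series

    def __post_init__(self) -> None:
        vals = self.code.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == -1.0) | (vals == 1.0)
        if not ok.all():
            bad = np.unique(vals[~ok])
            raise ValueError(f"trait codes must be -1/+1/NaN, got {bad}")

    @property
    def values(self) -> np.ndarray:
        return self.code.to_numpy(dtype=float)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_positive(self) -> int:
        return int((self.values == 1.0).sum())

    @property
    def n_negative(self) -> int:
        return int((self.values == -1.0).sum())

    def dropna(self) -> "TraitVector":
        return TraitVector(self.code.dropna())


@dataclass
class PhenomeMatrix:
    """Participants x phenotypes with per-column categories for one scan family.

    ``family_size`` is the Bonferroni denominator; it defaults to the number
    of columns but can be set larger (e.g. the study-declared family total)
    so corrected thresholds match the declared family even when only a subset
    of phenotypes is supplied.
    """

    data: pd.DataFrame
    category: np.ndarray = None  # type: ignore[assignment]
    family: str = "generic"
    family_size: int | None = None

    def __post_init__(self) -> None:
        if self.category is None:
            self.category = np.array(["uncategorized"] * self.data.shape[1], dtype=object)
        self.category = np.asarray(self.category, dtype=object)
        if len(self.category) != self.data.shape[1]:
            raise ValueError("category length must equal phenotype count")
        if self.family_size is None:
            self.family_size = self.data.shape[1]
        if self.family_size < self.data.shape[1]:
            raise ValueError(
                f"family_size {self.family_size} smaller than tested column "
                f"count {self.data.shape[1]}"
            )

    @property
    def n_phenotypes(self) -> int:
        return self.data.shape[1]
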