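"""Cohort preparation: trait recoding, exclusion filters, confound regression.

The raw diurnal-preference item has six response levels; the two morning
levels are coded -1 ("early bird"), the two evening levels +1 ("night owl"),
and the two non-answers become missing.  Participants whose codes disagree
between the two assessment instances, or who report any history of shift
work, are excluded.  Nuisance variation (body habitus, head size, motion,
scanner position, site, sleep measures) is regressed out of the brain
features by ordinary least squares, feature by feature.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import FeatureMatrix

__all__ = [
    "MORNING_LEVELS",
    "EVENING_LEVELS",
    "MISSING_LEVELS",
    "recode_trait",
    "recode_trait_series",
    "filter_concordant",
    "filter_shift_workers",
    "residualize",
    "encode_confounds",
]

MORNING_LEVELS = frozenset(
    {"definitely a morning person", "more a morning than an evening person"}
)
EVENING_LEVELS = frozenset(
    {"definitely an evening person", "more an evening than a morning person"}
)
MISSING_LEVELS = frozenset({"do not know", "prefer not to answer"})

#: Shift-work flag levels counting as positive evidence of exposure.
POSITIVE_SHIFT_LEVELS = frozenset({"sometimes", "usually", "always", "yes"})
NEGATIVE_SHIFT_LEVELS = frozenset({"never/rarely", "never", "no"})


def recode_trait(raw) -> float:
    """Map one 6-level response to -1 (morning), +1 (evening) or NaN.

    Raises ``ValueError`` naming the offending string for undeclared levels.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan
    level = str(raw).strip().lower()
    if level in MORNING_LEVELS:
        return -1.0
    if level in EVENING_LEVELS:
        return 1.0
    if level in MISSING_LEVELS:
        return np.nan
    raise ValueError(f"undeclared chronotype level: {raw!r}")


def recode_trait_series(raw: pd.Series) -> pd.Series:
    return raw.map(recode_trait).astype(float)


def filter_concordant(
    table: pd.DataFrame,
    instance0: str = "trait_instance0",
    instance2: str = "trait_instance2",
    recoded: bool = False,
) -> pd.Index:
    """Participant ids whose trait codes agree (and are non-missing) at both
    assessment instances; input order preserved."""
    for col in (instance0, instance2):
        if col not in table.columns:
            raise KeyError(f"missing trait column {col!r}")
    a = table[instance0] if recoded else recode_trait_series(table[instance0])
    b = table[instance2] if recoded else recode_trait_series(table[instance2])
    keep = a.notna() & b.notna() & (a == b)
    return table.index[keep]


def filter_shift_workers(
    table: pd.DataFrame,
    flag_columns=("shift_work_0", "shift_work_2", "night_shift_0", "night_shift_2"),
    positive_levels=POSITIVE_SHIFT_LEVELS,
) -> pd.Index:
    """Participant ids with no positive shift-work evidence in any flag column.

    A missing flag is treated as no evidence (the participant is retained);
    exclusion requires a declared positive level in at least one column.
    """
    missing_cols = [c for c in flag_columns if c not in table.columns]
    if missing_cols:
        raise KeyError(f"missing shift-work flag columns: {missing_cols}")
    positive = {str(v).strip().lower() for v in positive_levels}
    exposed = np.zeros(len(table), dtype=bool)
    for col in flag_columns:
        vals = table[col].map(
            lambda v: (
                False
                if v is None or (isinstance(v, float) and np.isnan(v))
                else str(v).strip().lower() in positive
            )
        )
        exposed |= vals.to_numpy(dtype=bool)
    return table.index[~exposed]


def encode_confounds(
    confounds: pd.DataFrame,
    categorical: tuple = (),
    zscore: bool = True,
) -> pd.DataFrame:
    """Numeric design from a confound table: one-hot categoricals (reference
    level dropped), optional z-scoring of all columns."""
    conf = confounds.copy()
    for col in categorical:
        dummies = pd.get_dummies(conf[col], prefix=col, drop_first=True, dtype=float)
        conf = pd.concat([conf.drop(columns=[col]), dummies], axis=1)
    conf = conf.astype(float)
    if conf.isna().any().any():
        bad = conf.columns[conf.isna().any()].tolist()
        raise ValueError(f"confound columns contain missing values: {bad}")
    if zscore:
        sd = conf.std(ddof=1)
        keep = sd > 0
        conf = (conf.loc[:, keep] - conf.loc[:, keep].mean()) / sd[keep]
    return conf


def residualize(
    x: FeatureMatrix,
    confounds: pd.DataFrame,
    categorical: tuple = (),
    zscore: bool = True,
) -> FeatureMatrix:
    """Replace each feature by its least-squares residual on [1 | confounds].

    Residual columns have exactly zero mean and zero sample correlation with
    every confound column (up to floating point).  Residuals are invariant to
    z-scoring of the confounds; it is kept on by default for conditioning.
    """
    if x.n_participants != len(confounds):
        raise ValueError(
            f"row mismatch: {x.n_participants} feature rows vs "
            f"{len(confounds)} confound rows"
        )
    if not x.participant_ids.equals(confounds.index):
        confounds = confounds.loc[x.participant_ids]
    conf = encode_confounds(confounds, categorical=categorical, zscore=zscore)
    design = np.column_stack([np.ones(len(conf)), conf.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            "confound design is rank-deficient (collinear columns); "
            "deduplicate or drop confounds before residualizing"
        )
    vals = x.values
    if np.isnan(vals).any():
        raise ValueError("feature matrix contains missing values; drop rows first")
    coef, *_ = np.linalg.lstsq(design, vals, rcond=None)
    resid = vals - design @ coef
    return FeatureMatrix(
        pd.DataFrame(resid, index=x.participant_ids, columns=x.data.columns),
        x.block_labels.copy(),
    )
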