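"""Mass-univariate profiling of latent mode scores.

Phenome-wide scans (PheWAS over behavior, DiaWAS over diagnosis phecodes,
MedWAS over medication categories) correlate each component's x-scores with
every phenotype column (Pearson; binary 0/1 columns reduce to point-biserial),
apply a per-family Bonferroni threshold alpha / family_size, and report
-log10 p for ranking and plotting.  Group differences use two-sample t-tests
and age structure is summarized as per-bracket score means and SDs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PhenomeMatrix
from .pls import ModeScoreSet

__all__ = [
    "AssociationRecord",
    "AgeBracketSummary",
    "scan",
    "group_difference",
    "stratify_age",
]

_P_FLOOR = np.finfo(float).tiny


@dataclass
class AssociationRecord:
    component: int
    phenotype_id: str
    category: str
    family: str
    n_used: int
    r: float
    p: float
    neg_log10_p: float
    passes_bonferroni: bool
    p_floored: bool = False
    zero_variance: bool = False


def _pearson_with_p(a: np.ndarray, b: np.ndarray):
    """Pearson r and two-sided p via the t transform with n-2 df."""
    n = a.shape[0]
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt((ac @ ac) * (bc @ bc))
    if denom == 0 or n < 3:
        return np.nan, np.nan
    r = float(np.clip((ac @ bc) / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def scan(
    scores: ModeScoreSet,
    phenome: PhenomeMatrix,
    alpha: float = 0.05,
    count_tested_only: bool = False,
) -> pd.DataFrame:
    """Correlate every component with every phenotype, Bonferroni-corrected.

    Missing phenotype values are handled pairwise-complete (per-test
    ``n_used``).  The multiplicity denominator is the family's declared
    ``family_size``; with ``count_tested_only`` it is instead the number of
    non-degenerate columns actually tested.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    svals = scores.values
    if svals.shape[0] != phenome.data.shape[0]:
        raise ValueError("scores and phenome are not aligned on participants")
    pvals_matrix = phenome.data.to_numpy(dtype=float)

    zero_var = []
    for j in range(phenome.n_phenotypes):
        col = pvals_matrix[:, j]
        col = col[~np.isnan(col)]
        zero_var.append(col.size < 3 or np.ptp(col) == 0)
    family_size = (
        int(phenome.n_phenotypes - sum(zero_var))
        if count_tested_only
        else int(phenome.family_size)
    )
    threshold = alpha / max(family_size, 1)

    records = []
    for k in range(scores.n_components):
        s = svals[:, k]
        for j, name in enumerate(phenome.data.columns):
            col = pvals_matrix[:, j]
            ok = ~np.isnan(col) & ~np.isnan(s)
            n_used = int(ok.sum())
            if zero_var[j]:
                records.append(
                    AssociationRecord(
                        component=k + 1,
                        phenotype_id=str(name),
                        category=str(phenome.category[j]),
                        family=phenome.family,
                        n_used=n_used,
                        r=np.nan,
                        p=np.nan,
                        neg_log10_p=np.nan,
                        passes_bonferroni=False,
                        zero_variance=True,
                    )
                )
                continue
            r, p = _pearson_with_p(s[ok], col[ok])
            floored = bool(p < _P_FLOOR) if np.isfinite(p) else False
            p_use = max(p, _P_FLOOR)
            records.append(
                AssociationRecord(
                    component=k + 1,
                    phenotype_id=str(name),
                    category=str(phenome.category[j]),
                    family=phenome.family,
                    n_used=n_used,
                    r=r,
                    p=p,
                    neg_log10_p=float(-np.log10(p_use)),
                    passes_bonferroni=bool(np.isfinite(p) and p < threshold),
                    p_floored=floored,
                )
            )
    out = pd.DataFrame([r.__dict__ for r in records])
    out.attrs["alpha"] = alpha
    out.attrs["family_size"] = family_size
    out.attrs["threshold"] = threshold
    return out


def group_difference(
    scores: ModeScoreSet,
    group,
    variant: str = "student",
) -> pd.DataFrame:
    """Two-sample t-test per component between group 1 and group 0.

    Student's pooled-variance test by default; Welch optional.  The sign
    convention is mean(group 1) minus mean(group 0).
    """
    g = np.asarray(group, dtype=float)
    svals = scores.values
    if g.shape[0] != svals.shape[0]:
        raise ValueError("group labels and scores are not aligned")
    labels = np.unique(g[~np.isnan(g)])
    if labels.size != 2:
        raise ValueError(f"need exactly 2 group labels, got {labels}")
    g0, g1 = labels  # larger label is "group 1"
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    rows = []
    for k in range(svals.shape[1]):
        a = svals[g == g1, k]
        b = svals[g == g0, k]
        if a.size < 2 or b.size < 2:
            raise ValueError("each group needs at least 2 members")
        t, p = stats.ttest_ind(a, b, equal_var=(variant == "student"))
        rows.append(
            {
                "component": k + 1,
                "t": float(t),
                "p": float(p),
                "mean_group1": float(a.mean()),
                "mean_group0": float(b.mean()),
                "n_group1": int(a.size),
                "n_group0": int(b.size),
            }
        )
    return pd.DataFrame(rows).set_index("component")


@dataclass
class AgeBracketSummary:
    bracket: tuple  # [low, high), closed-left / open-right
    label: str
    n: int
    mean_score: np.ndarray  # per component
    sd_score: np.ndarray  # per component, sample SD (ddof=1)


def stratify_age(
    scores: ModeScoreSet,
    age,
    brackets=((40, 50), (50, 55), (55, 60), (60, 65), (65, 70)),
) -> tuple[list[AgeBracketSummary], int]:
    """Mean and SD of each component's scores within half-open age brackets.

    A shared printed endpoint (e.g. "40-50, 50-55") goes to the upper
    bracket: intervals are [low, high).  Returns the per-bracket summaries
    and the count of participants outside every bracket.
    """
    age = np.asarray(age, dtype=float)
    svals = scores.values
    if age.shape[0] != svals.shape[0]:
        raise ValueError("age vector and scores are not aligned")
    br = [(float(lo), float(hi)) for lo, hi in brackets]
    if any(hi <= lo for lo, hi in br):
        raise ValueError("each bracket needs low < high")
    for (lo1, hi1), (lo2, hi2) in zip(br, br[1:]):
        if lo2 < hi1:
            raise ValueError("brackets must be ordered and non-overlapping")

    summaries = []
    assigned = np.zeros(age.shape[0], dtype=bool)
    for lo, hi in br:
        mask = (age >= lo) & (age < hi)
        assigned |= mask
        sub = svals[mask]
        summaries.append(
            AgeBracketSummary(
                bracket=(lo, hi),
                label=f"{lo:g}-{hi:g}",
                n=int(mask.sum()),
                mean_score=sub.mean(0) if mask.any() else np.full(svals.shape[1], np.nan),
                sd_score=(
                    sub.std(0, ddof=1)
                    if mask.sum() > 1
                    else np.full(svals.shape[1], np.nan)
                ),
            )
        )
    return summaries, int((~assigned).sum())


def bracket_table(summaries: list[AgeBracketSummary]) -> pd.DataFrame:
    """Long-format frame: one row per bracket x component."""
    rows = []
    for s in summaries:
        for k in range(len(s.mean_score)):
            rows.append(
                {
                    "bracket": s.label,
                    "component": k + 1,
                    "n": s.n,
                    "mean_score": s.mean_score[k],
                    "sd_score": s.sd_score[k],
                }
            )
    return pd.DataFrame(rows)
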