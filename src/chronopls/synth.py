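"""Synthetic two-cohort generator with planted brain-trait modes.

The generator emulates the statistical skeleton of a population-imaging
chronotype study: an n x p feature matrix made of labelled blocks (GMV / FA /
FC), a small number of planted orthonormal low-rank modes whose latent scores
drive a dichotomized trait (~2:1 class imbalance), sex- and age-structured
mode expression, additive linear confound effects with known coefficients, a
sparse mode-linked phenome, and a second "transfer" cohort that shares only
the GMV block and reverses the age trends.  Because every planted quantity is
returned to the caller, each downstream stage (PLS fit, permutation test,
bootstrap CIs, cross-cohort projection, phenome scan) can be validated
against ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FeatureMatrix, PhenomeMatrix, TraitVector

__all__ = [
    "SyntheticTruth",
    "SyntheticCohort",
    "TransferCohort",
    "binarization_attenuation",
    "trait_noise_for_latent_r",
    "generate_cohort",
    "generate_phenome",
    "generate_transfer_cohort",
]

DEFAULT_BLOCK_SIZES = {"GMV": 139, "FA": 48, "FC": 210}
#: Eveningness fraction observed in the source cohort (9,035 of 27,030).
DEFAULT_PREVALENCE = 0.334


def binarization_attenuation(prevalence: float) -> float:
    """Point-biserial attenuation factor for a quantile-dichotomized normal.

    If a latent normal variable correlates rho with some score, the -1/+1
    code obtained by cutting it at the top-``prevalence`` quantile correlates
    approximately ``rho * phi(z_q) / sqrt(q (1-q))`` with that score, where
    ``z_q`` is the cut point.  Used to calibrate generator noise so the
    *binarized* trait lands at a target latent correlation.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    z = stats.norm.ppf(1.0 - prevalence)
    return float(stats.norm.pdf(z) / np.sqrt(prevalence * (1.0 - prevalence)))


def trait_noise_for_latent_r(
    target_r: float,
    trait_weights,
    prevalence: float = DEFAULT_PREVALENCE,
) -> float:
    """Trait noise SD s.t. mode 1's *binarized* latent correlation ~= target_r.

    Solves ``target_r = A(prevalence) * beta_1 / sqrt(sum(beta^2) + s^2)``
    for s, where A is :func:`binarization_attenuation`.
    """
    beta = np.asarray(trait_weights, dtype=float)
    rho_cont = target_r / binarization_attenuation(prevalence)
    if not 0.0 < rho_cont < 1.0:
        raise ValueError(f"target_r={target_r} unattainable at this prevalence")
    s2 = beta[0] ** 2 / rho_cont**2 - float(beta @ beta)
    if s2 <= 0.0:
        raise ValueError(
            f"target_r={target_r} too large for trait_weights={trait_weights}"
        )
    return float(np.sqrt(s2))


@dataclass
class SyntheticTruth:
    """Generative parameters plus (after generation) the planted quantities.

    mode_strengths, trait_weights, sex_effect and age_slope all have one
    entry per planted mode.  ``sex_effect`` is the mean latent-score shift
    between sexes; ``age_slope`` is the latent-score trend per unit of age
    (years for the source cohort, months for the transfer cohort).
    """

    mode_strengths: tuple = (4.0, 3.0)
    trait_weights: tuple = (1.0, 0.5)
    noise_sd: float = 1.0
    trait_noise_sd: float | None = None  # None -> calibrated to latent r ~ 0.1
    trait_prevalence: float = DEFAULT_PREVALENCE
    sex_effect: tuple = (0.0, 0.5)
    age_slope: tuple = (0.02, -0.02)
    age_range: tuple = (40.0, 70.0)
    confound_effect_sd: float = 0.5
    block_sizes: dict = field(default_factory=lambda: dict(DEFAULT_BLOCK_SIZES))
    seed: int = 0
    # populated by generate_cohort:
    planted_loadings: np.ndarray | None = None  # p x K, orthonormal columns
    latent_scores: np.ndarray | None = None  # n x K
    confound_coefs: np.ndarray | None = None  # n_confounds x K... x p

    def __post_init__(self) -> None:
        k = len(self.mode_strengths)
        for name in ("trait_weights", "sex_effect", "age_slope"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} must have one entry per mode ({k})")
        if any(s <= 0 for s in self.mode_strengths):
            raise ValueError("mode strengths must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 < self.trait_prevalence < 1.0:
            raise ValueError("trait_prevalence must lie in (0, 1)")
        if self.trait_noise_sd is None:
            self.trait_noise_sd = trait_noise_for_latent_r(
                0.1, self.trait_weights, self.trait_prevalence
            )

    @property
    def n_modes(self) -> int:
        return len(self.mode_strengths)

    @property
    def n_features(self) -> int:
        return int(sum(self.block_sizes.values()))

    @classmethod
    def for_latent_r(cls, target_r: float, **kwargs) -> "SyntheticTruth":
        """Truth whose mode-1 binarized latent correlation is ~= target_r."""
        probe = cls(trait_noise_sd=1.0, **kwargs)
        noise = trait_noise_for_latent_r(
            target_r, probe.trait_weights, probe.trait_prevalence
        )
        return cls(trait_noise_sd=noise, **kwargs)

    def to_jsonable(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, np.ndarray):
                v = v.tolist()
            elif isinstance(v, tuple):
                v = list(v)
            out[f.name] = v
        return out


@dataclass
class SyntheticCohort:
    features: FeatureMatrix
    trait: TraitVector
    confounds: pd.DataFrame  # nuisance columns only (bmi, head size, motion...)
    covariates: pd.DataFrame  # age, sex: analysis variables, never residualized
    truth: SyntheticTruth


@dataclass
class TransferCohort:
    features: FeatureMatrix  # shared block only
    age: pd.Series
    covariates: pd.DataFrame
    truth: SyntheticTruth


def _orthonormal_loadings(rng: np.random.Generator, p: int, k: int) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((p, k)))
    # fix each column's sign so the largest-|.| entry is positive
    flip = np.sign(q[np.abs(q).argmax(axis=0), np.arange(k)])
    return q * flip


def _feature_names(block_sizes: dict) -> tuple[list[str], np.ndarray]:
    names, labels = [], []
    for block, size in block_sizes.items():
        names.extend(f"{block}_{i:03d}" for i in range(int(size)))
        labels.extend([block] * int(size))
    return names, np.array(labels, dtype=object)


CONFOUND_NAMES = ["bmi", "head_size", "motion_task", "motion_rest", "table_position"]
_CONFOUND_LOC = np.array([27.0, 1500.0, 0.2, 0.15, 50.0])
_CONFOUND_SCALE = np.array([4.0, 100.0, 0.05, 0.04, 8.0])


def generate_cohort(
    n: int,
    block_sizes: dict | None = None,
    truth: SyntheticTruth | None = None,
    seed: int | None = None,
) -> SyntheticCohort:
    """Simulate one cohort with planted low-rank trait-linked modes.

    X = sum_k sigma_k t_k p_k' + noise_sd * E + C_z @ Gamma, with t_k
    standard-normal latent scores carrying per-mode sex shifts and linear age
    trends; the trait is +1 for the top ``trait_prevalence`` quantile of the
    latent trait y* = sum_k beta_k t_k + eps and -1 otherwise.  Deterministic
    under (parameters, seed).
    """
    if n < 10:
        raise ValueError("n must be at least 10")
    truth = truth if truth is not None else SyntheticTruth()
    if block_sizes is not None:
        truth = dataclasses.replace(truth, block_sizes=dict(block_sizes))
    if seed is not None:
        truth = dataclasses.replace(truth, seed=int(seed))
    k, p = truth.n_modes, truth.n_features
    if k > p:
        raise ValueError(f"{k} modes exceed {p} total features")
    if any(int(s) <= 0 for s in truth.block_sizes.values()):
        raise ValueError("block sizes must be positive")

    rng = np.random.default_rng(truth.seed)
    loadings = _orthonormal_loadings(rng, p, k)

    sex = rng.integers(0, 2, size=n).astype(float)  # 0 = female, 1 = male
    lo, hi = truth.age_range
    age = rng.uniform(lo, hi, size=n)
    scores = rng.standard_normal((n, k))
    scores += np.outer(sex - 0.5, np.asarray(truth.sex_effect, dtype=float))
    scores += np.outer(age - (lo + hi) / 2.0, np.asarray(truth.age_slope, dtype=float))

    sigma = np.asarray(truth.mode_strengths, dtype=float)
    x = (scores * sigma) @ loadings.T
    x += truth.noise_sd * rng.standard_normal((n, p))

    raw_conf = _CONFOUND_LOC + _CONFOUND_SCALE * rng.standard_normal(
        (n, len(CONFOUND_NAMES))
    )
    conf_z = (raw_conf - raw_conf.mean(0)) / raw_conf.std(0, ddof=1)
    gamma = truth.confound_effect_sd * rng.standard_normal((len(CONFOUND_NAMES), p))
    x += conf_z @ gamma

    beta = np.asarray(truth.trait_weights, dtype=float)
    latent_trait = scores @ beta + truth.trait_noise_sd * rng.standard_normal(n)
    n_pos = int(round(truth.trait_prevalence * n))
    code = np.full(n, -1.0)
    code[np.argsort(latent_trait)[::-1][:n_pos]] = 1.0

    ids = pd.Index([f"sub{i:06d}" for i in range(n)], name="participant_id")
    names, labels = _feature_names(truth.block_sizes)
    features = FeatureMatrix(pd.DataFrame(x, index=ids, columns=names), labels)
    trait = TraitVector(pd.Series(code, index=ids, name="trait"))
    confounds = pd.DataFrame(raw_conf, index=ids, columns=CONFOUND_NAMES)
    covariates = pd.DataFrame({"age": age, "sex": sex}, index=ids)
    truth = dataclasses.replace(
        truth, planted_loadings=loadings, latent_scores=scores, confound_coefs=gamma
    )
    return SyntheticCohort(features, trait, confounds, covariates, truth)


def generate_phenome(
    latent_scores: np.ndarray,
    n_pheno: int,
    n_linked_per_mode: int,
    effect_r: float = 0.15,
    binary_fraction: float = 0.3,
    category_labels=("cognition", "lifestyle", "mood", "physical"),
    family: str = "behavior",
    family_size: int | None = None,
    index=None,
    seed: int = 0,
) -> PhenomeMatrix:
    """Simulate a phenome with ``n_linked_per_mode`` mode-linked columns.

    Linked continuous phenotypes are ``effect_r * z(t_k) + sqrt(1-r^2) *
    noise``; binary ones threshold the same construct at its 70th percentile.
    Column names encode the ground truth (``mode<k>``/``noise``, ``cont``/
    ``bin``) so recovery tests need no side channel.
    """
    scores = np.asarray(latent_scores, dtype=float)
    n, k = scores.shape
    if not 0.0 < effect_r < 1.0:
        raise ValueError("effect_r must lie in (0, 1)")
    if n_linked_per_mode * k > n_pheno:
        raise ValueError("more linked phenotypes than n_pheno")

    rng = np.random.default_rng(seed)
    z = (scores - scores.mean(0)) / scores.std(0, ddof=0)
    cols, names = [], []
    n_linked = n_linked_per_mode * k
    n_bin_linked = int(round(binary_fraction * n_linked_per_mode))
    for mode in range(k):
        for j in range(n_linked_per_mode):
            construct = effect_r * z[:, mode] + np.sqrt(1 - effect_r**2) * (
                rng.standard_normal(n)
            )
            if j < n_bin_linked:
                col = (construct > np.quantile(construct, 0.7)).astype(float)
                kind = "bin"
            else:
                col, kind = construct, "cont"
            cols.append(col)
            names.append(f"ph_mode{mode + 1}_{kind}_{len(names):04d}")
    n_noise = n_pheno - n_linked
    n_bin_noise = int(round(binary_fraction * n_noise))
    for j in range(n_noise):
        construct = rng.standard_normal(n)
        if j < n_bin_noise:
            col = (construct > np.quantile(construct, 0.7)).astype(float)
            kind = "bin"
        else:
            col, kind = construct, "cont"
        cols.append(col)
        names.append(f"ph_noise_{kind}_{len(names):04d}")

    data = pd.DataFrame(
        np.column_stack(cols) if cols else np.empty((n, 0)),
        index=index if index is not None else pd.RangeIndex(n),
        columns=names,
    )
    category = np.array(
        [category_labels[i % len(category_labels)] for i in range(n_pheno)],
        dtype=object,
    )
    return PhenomeMatrix(data, category, family=family, family_size=family_size)


def generate_transfer_cohort(
    truth: SyntheticTruth,
    n2: int,
    shared_block: str = "GMV",
    age_range: tuple = (100.0, 140.0),
    reversed_age_slope=None,
    seed: int = 1,
) -> TransferCohort:
    """Second cohort sharing only ``shared_block``, with its own age trends.

    The planted loadings are the source cohort's, restricted to the shared
    block's rows; by default the per-mode age slopes are the negated source
    slopes, emulating opposite score-vs-age trends between cohorts.
    """
    if truth.planted_loadings is None:
        raise ValueError("truth must come from generate_cohort (loadings missing)")
    if shared_block not in truth.block_sizes:
        raise KeyError(
            f"unknown block {shared_block!r}; have {sorted(truth.block_sizes)}"
        )
    if reversed_age_slope is None:
        reversed_age_slope = tuple(-a for a in truth.age_slope)
    if len(reversed_age_slope) != truth.n_modes:
        raise ValueError("reversed_age_slope needs one entry per mode")

    names, labels = _feature_names(truth.block_sizes)
    keep = np.array([lab == shared_block for lab in labels])
    loadings_sub = truth.planted_loadings[keep]

    rng = np.random.default_rng(seed)
    k = truth.n_modes
    sex = rng.integers(0, 2, size=n2).astype(float)
    lo, hi = age_range
    age = rng.uniform(lo, hi, size=n2)
    scores = rng.standard_normal((n2, k))
    scores += np.outer(sex - 0.5, np.asarray(truth.sex_effect, dtype=float))
    scores += np.outer(
        age - (lo + hi) / 2.0, np.asarray(reversed_age_slope, dtype=float)
    )
    sigma = np.asarray(truth.mode_strengths, dtype=float)
    x = (scores * sigma) @ loadings_sub.T
    x += truth.noise_sd * rng.standard_normal((n2, int(keep.sum())))

    ids = pd.Index([f"tfr{i:06d}" for i in range(n2)], name="participant_id")
    sub_names = [nm for nm, m in zip(names, keep) if m]
    features = FeatureMatrix(
        pd.DataFrame(x, index=ids, columns=sub_names), labels[keep]
    )
    truth2 = dataclasses.replace(
        truth,
        age_slope=tuple(reversed_age_slope),
        age_range=(lo, hi),
        block_sizes={shared_block: int(keep.sum())},
        planted_loadings=loadings_sub,
        latent_scores=scores,
        seed=int(seed),
    )
    covariates = pd.DataFrame({"age": age, "sex": sex}, index=ids)
    return TransferCohort(features, pd.Series(age, index=ids, name="age"), covariates, truth2)
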