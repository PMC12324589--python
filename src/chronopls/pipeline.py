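"""End-to-end orchestration: prep -> PLS -> permutation -> bootstrap -> scans
-> cross-cohort projection -> age stratification.

A single master seed fans out to fixed per-stage child seeds (SeedSequence
keyed on stage index), so any stage can be rerun independently yet the whole
run is bit-reproducible.  Every output table carries provenance comment lines
(package version, config hash, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import FeatureMatrix, PhenomeMatrix, TraitVector
from .inference import bootstrap_loadings, permutation_test
from .io import read_feature_matrix, read_table, save_model, write_table
from .phenome import bracket_table, group_difference, scan, stratify_age
from .pls import ModeScoreSet, align_signs, fit_pls, latent_correlation
from .prep import (
    filter_concordant,
    filter_shift_workers,
    recode_trait_series,
    residualize,
)
from .synth import SyntheticTruth, generate_cohort, generate_phenome, generate_transfer_cohort
from .transfer import project_cohort, restrict_model

__all__ = ["RunConfig", "run_pipeline", "make_demo", "stage_seed"]

_STAGES = {"cohort": 0, "phenome": 1, "transfer": 2, "permutation": 3, "bootstrap": 4}

DEFAULT_BRACKETS_SOURCE = ((40, 50), (50, 55), (55, 60), (60, 65), (65, 70))
DEFAULT_BRACKETS_TARGET = ((100, 110), (110, 120), (120, 130), (130, 140))


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2^31."""
    ss = np.random.SeedSequence([int(master), _STAGES[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything one pipeline run needs; hashable for provenance."""

    out_dir: str = "run"
    seed: int = 0
    n_components: int = 5
    n_perm: int = 1000
    n_boot: int = 1000
    alpha_mode: float = 0.001
    alpha_scan: float = 0.05
    percentiles: tuple = (5.0, 95.0)
    centering: str = "target"
    scale: bool = True
    # synth mode (used when input paths are absent)
    synth: bool = True
    n: int = 1000
    n_target: int = 500
    target_latent_r: float | None = None  # None -> SyntheticTruth default (~0.1)
    truth_overrides: dict = field(default_factory=dict)
    n_pheno: int = 200
    n_linked_per_mode: int = 5
    phenome_effect_r: float = 0.15
    shared_block: str = "GMV"
    brackets_source: tuple = DEFAULT_BRACKETS_SOURCE
    brackets_target: tuple = DEFAULT_BRACKETS_TARGET
    # file mode
    participants_path: str | None = None
    features_path: str | None = None
    confounds_path: str | None = None
    phenome_path: str | None = None
    phenome_family: str = "behavior"
    phenome_family_size: int | None = None
    target_features_path: str | None = None
    target_age_column: str = "age"

    def __post_init__(self) -> None:
        if self.n_components < 1 or self.n_perm < 1 or self.n_boot < 2:
            raise ValueError("n_components >= 1, n_perm >= 1, n_boot >= 2 required")
        for a in (self.alpha_mode, self.alpha_scan):
            if not 0.0 < a < 1.0:
                raise ValueError("alpha levels must lie in (0, 1)")
        lo, hi = self.percentiles
        if not 0 <= lo < hi <= 100:
            raise ValueError("percentiles must satisfy 0 <= low < high <= 100")
        if self.centering not in ("target", "source", "none"):
            raise ValueError("centering must be target|source|none")
        paths = [
            self.participants_path,
            self.features_path,
            self.confounds_path,
            self.target_features_path,
        ]
        if any(p is not None for p in paths):
            self.synth = False
            for p in (self.participants_path, self.features_path):
                if p is None:
                    raise ValueError(
                        "file mode needs participants_path and features_path"
                    )
                if not Path(p).exists():
                    raise FileNotFoundError(p)
            for p in (self.confounds_path, self.phenome_path, self.target_features_path):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("percentiles", "brackets_source", "brackets_target"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(
                    tuple(b) if isinstance(b, (list, tuple)) else b for b in raw[key]
                )
        return cls(**raw)

    def hash(self) -> str:
        """Hash of the analysis-relevant parameters (out_dir excluded)."""
        doc = {}
        for f in dataclasses.fields(self):
            if f.name == "out_dir":
                continue
            v = getattr(self, f.name)
            doc[f.name] = list(v) if isinstance(v, tuple) else v
        blob = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict:
    return {
        "package": f"chronopls {__version__}",
        "config_hash": config.hash(),
        "seed": config.seed,
    }


def _load_file_cohort(config: RunConfig):
    participants = read_table(config.participants_path)
    features = read_feature_matrix(config.features_path)
    prep_report = {"n_raw": int(len(participants))}

    concordant = filter_concordant(participants)
    prep_report["n_after_concordance"] = int(len(concordant))
    non_shift = filter_shift_workers(participants)
    retained = concordant.intersection(non_shift, sort=False)
    prep_report["n_after_shift_filter"] = int(len(retained))
    retained = retained.intersection(features.participant_ids, sort=False)
    complete = ~features.data.loc[retained].isna().any(axis=1)
    retained = retained[complete.to_numpy()]
    prep_report["n_final"] = int(len(retained))

    features = features.select_rows(retained)
    code = recode_trait_series(participants.loc[retained, "trait_instance2"])
    trait = TraitVector(code.rename("trait"))

    confounds = None
    if config.confounds_path is not None:
        confounds = read_table(config.confounds_path).loc[retained]
    covariates = participants.loc[retained, ["age", "sex"]].astype(float)

    phenome = None
    if config.phenome_path is not None:
        ph = read_table(config.phenome_path).loc[retained]
        phenome = PhenomeMatrix(
            ph,
            family=config.phenome_family,
            family_size=config.phenome_family_size,
        )

    target = None
    target_age = None
    if config.target_features_path is not None:
        tfm = read_feature_matrix(config.target_features_path)
        if config.target_age_column in tfm.data.columns:
            target_age = tfm.data[config.target_age_column].astype(float)
            tfm = FeatureMatrix(
                tfm.data.drop(columns=[config.target_age_column]),
                None,
            )
        target = tfm
    return features, trait, confounds, covariates, phenome, target, target_age, prep_report


def _make_synth_cohort(config: RunConfig):
    if config.target_latent_r is not None:
        truth = SyntheticTruth.for_latent_r(
            config.target_latent_r,
            seed=stage_seed(config.seed, "cohort"),
            **config.truth_overrides,
        )
    else:
        truth = SyntheticTruth(
            seed=stage_seed(config.seed, "cohort"), **config.truth_overrides
        )
    cohort = generate_cohort(config.n, truth=truth)
    phenome = generate_phenome(
        cohort.truth.latent_scores,
        n_pheno=config.n_pheno,
        n_linked_per_mode=config.n_linked_per_mode,
        effect_r=config.phenome_effect_r,
        index=cohort.features.participant_ids,
        seed=stage_seed(config.seed, "phenome"),
    )
    tcohort = generate_transfer_cohort(
        cohort.truth,
        n2=config.n_target,
        shared_block=config.shared_block,
        seed=stage_seed(config.seed, "transfer"),
    )
    prep_report = {"n_raw": config.n, "n_final": config.n}
    return (
        cohort.features,
        cohort.trait,
        cohort.confounds,
        cohort.covariates,
        phenome,
        tcohort.features,
        tcohort.age,
        prep_report,
        cohort.truth,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns the machine-readable report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    report: dict = {
        "config": {
            f.name: (list(v) if isinstance(v, tuple) else v)
            for f in dataclasses.fields(config)
            if not isinstance((v := getattr(config, f.name)), dict)
        },
        "config_hash": config.hash(),
        "package_version": __version__,
        "seed": config.seed,
    }

    truth = None
    if config.synth:
        (
            features,
            trait,
            confounds,
            covariates,
            phenome,
            target,
            target_age,
            prep_report,
            truth,
        ) = _make_synth_cohort(config)
    else:
        (
            features,
            trait,
            confounds,
            covariates,
            phenome,
            target,
            target_age,
            prep_report,
        ) = _load_file_cohort(config)
    report["prep"] = prep_report
    (out / "prep_report.json").write_text(json.dumps(prep_report, indent=2))

    keep = ~trait.missing_mask
    if not keep.all():
        ids = features.participant_ids[keep]
        features = features.select_rows(ids)
        trait = TraitVector(trait.code.loc[ids])
        covariates = covariates.loc[ids]
        if confounds is not None:
            confounds = confounds.loc[ids]
        if phenome is not None:
            phenome = PhenomeMatrix(
                phenome.data.loc[ids],
                phenome.category,
                phenome.family,
                phenome.family_size,
            )
    if confounds is not None:
        features = residualize(features, confounds)

    n_comp = min(config.n_components, features.n_features, features.n_participants - 1)
    model = fit_pls(features, trait, n_components=n_comp, scale=config.scale)
    model = align_signs(model, "trait-positive", y=trait)
    rho = latent_correlation(model, trait)
    save_model(model, out / "model.json", provenance=prov)

    sig = permutation_test(
        features,
        trait,
        n_components=n_comp,
        n_perm=config.n_perm,
        alpha=config.alpha_mode,
        seed=stage_seed(config.seed, "permutation"),
        scale=config.scale,
    )
    modes = pd.DataFrame(
        {
            "component": [s.component for s in sig],
            "observed_rho": [s.observed_rho for s in sig],
            "p_value": [s.p_value for s in sig],
            "significant": [s.significant for s in sig],
        }
    ).set_index("component")
    write_table(modes, out / "modes.tsv", provenance=prov)
    significant_components = [s.component for s in sig if s.significant]
    report["modes"] = modes.reset_index().to_dict(orient="records")
    report["significant_components"] = significant_components

    stability = bootstrap_loadings(
        features,
        trait,
        n_boot=config.n_boot,
        percentiles=config.percentiles,
        seed=stage_seed(config.seed, "bootstrap"),
        scale=config.scale,
        reference=model,
    )
    loadings = pd.DataFrame(
        {
            "feature": np.repeat(model.feature_names, n_comp),
            "block": np.repeat(model.block_labels, n_comp),
            "component": np.tile(np.arange(1, n_comp + 1), model.n_features),
            "loading": model.x_loadings.ravel(),
            "ci_low": stability.ci_low.ravel(),
            "ci_high": stability.ci_high.ravel(),
            "significant": stability.significant_mask.ravel(),
        }
    )
    write_table(loadings, out / "loadings.tsv", provenance=prov, index=False)
    report["n_significant_loadings_per_component"] = (
        stability.significant_mask.sum(axis=0).astype(int).tolist()
    )

    scores = ModeScoreSet(
        pd.DataFrame(
            model.x_scores,
            index=features.participant_ids,
            columns=[f"comp{k+1}" for k in range(n_comp)],
        ),
        trait_correlation=rho["r"].to_numpy(),
    )
    write_table(scores.scores, out / "scores.tsv", provenance=prov)

    if phenome is not None:
        assoc = scan(scores, phenome, alpha=config.alpha_scan)
        write_table(
            assoc, out / f"scan_{phenome.family}.tsv", provenance=prov, index=False
        )
        tested = assoc[~assoc["zero_variance"]]
        top = (
            tested.sort_values("p")
            .groupby("component", sort=True)
            .head(3)[["component", "phenotype_id", "r", "p", "passes_bonferroni"]]
        )
        report["scan"] = {
            "family": phenome.family,
            "family_size": int(assoc.attrs["family_size"]),
            "n_bonferroni_hits": int(tested["passes_bonferroni"].sum()),
            "top_associations": top.to_dict(orient="records"),
        }

    if "sex" in covariates.columns and covariates["sex"].nunique() == 2:
        sexdiff = group_difference(scores, covariates["sex"])
        write_table(sexdiff, out / "sex_difference.tsv", provenance=prov)
        report["sex_difference"] = sexdiff.reset_index().to_dict(orient="records")

    summaries, unassigned = stratify_age(
        scores, covariates["age"], brackets=config.brackets_source
    )
    src_brackets = bracket_table(summaries)
    write_table(src_brackets, out / "brackets_source.tsv", provenance=prov, index=False)
    report["brackets_source_unassigned"] = unassigned

    if target is not None:
        rmodel = restrict_model(model, config.shared_block)
        tscores = project_cohort(rmodel, target, centering=config.centering)
        write_table(tscores.scores, out / "target_scores.tsv", provenance=prov)
        if target_age is not None:
            tsummaries, t_unassigned = stratify_age(
                tscores, target_age, brackets=config.brackets_target
            )
            write_table(
                bracket_table(tsummaries),
                out / "brackets_target.tsv",
                provenance=prov,
                index=False,
            )
            report["brackets_target_unassigned"] = t_unassigned
        report["transfer"] = {
            "shared_block": config.shared_block,
            "n_target": int(tscores.scores.shape[0]),
            "condition_number": rmodel.condition_number,
        }

    report["generated_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report


# ---------------------------------------------------------------------------
# demo dataset
# ---------------------------------------------------------------------------

_MORNING_RAW = ("Definitely a morning person", "More a morning than an evening person")
_EVENING_RAW = ("Definitely an evening person", "More an evening than a morning person")


def make_demo(seed: int = 0, out_dir: str = "demo", n: int = 3000, n_decoys: int = 20,
              n_target: int = 500) -> dict:
    """Write a miniature two-cohort dataset plus a ready-to-run config.

    Planted effects are deliberately strong (mode-1 binarized latent r ~0.35)
    and n large enough relative to the 397 features that both planted modes
    clear the permutation threshold; the decoy participants exercise the
    concordance and shift-work filters.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    truth = SyntheticTruth.for_latent_r(
        0.35, trait_weights=(1.0, 0.75), seed=stage_seed(seed, "cohort")
    )
    cohort = generate_cohort(n, truth=truth)
    phenome = generate_phenome(
        cohort.truth.latent_scores,
        n_pheno=120,
        n_linked_per_mode=5,
        effect_r=0.3,
        index=cohort.features.participant_ids,
        seed=stage_seed(seed, "phenome"),
    )
    tcohort = generate_transfer_cohort(
        cohort.truth, n2=n_target, seed=stage_seed(seed, "transfer")
    )

    code = cohort.trait.values
    raw0 = [
        rng.choice(_MORNING_RAW) if c == -1 else rng.choice(_EVENING_RAW) for c in code
    ]
    participants = pd.DataFrame(
        {
            "trait_instance0": raw0,
            "trait_instance2": raw0,  # concordant by construction
            "shift_work_0": "Never/rarely",
            "shift_work_2": "Never/rarely",
            "night_shift_0": "Never/rarely",
            "night_shift_2": "Never/rarely",
            "age": cohort.covariates["age"],
            "sex": cohort.covariates["sex"],
        },
        index=cohort.features.participant_ids,
    )
    # decoys: half discordant between instances, half shift workers
    decoys = []
    decoy_feats = []
    for i in range(n_decoys):
        pid = f"decoy{i:04d}"
        discordant = i % 2 == 0
        decoys.append(
            {
                "participant_id": pid,
                "trait_instance0": rng.choice(_MORNING_RAW),
                "trait_instance2": (
                    rng.choice(_EVENING_RAW) if discordant else rng.choice(_MORNING_RAW)
                ),
                "shift_work_0": "Never/rarely" if discordant else "Usually",
                "shift_work_2": "Never/rarely",
                "night_shift_0": "Never/rarely",
                "night_shift_2": "Never/rarely",
                "age": float(rng.uniform(40, 70)),
                "sex": float(rng.integers(0, 2)),
            }
        )
        decoy_feats.append(rng.standard_normal(cohort.features.n_features))
    decoy_frame = pd.DataFrame(decoys).set_index("participant_id")
    participants = pd.concat([participants, decoy_frame])

    feats = pd.concat(
        [
            cohort.features.data,
            pd.DataFrame(
                np.array(decoy_feats),
                index=decoy_frame.index,
                columns=cohort.features.data.columns,
            ),
        ]
    )
    decoy_conf = pd.DataFrame(
        rng.standard_normal((n_decoys, cohort.confounds.shape[1])),
        index=decoy_frame.index,
        columns=cohort.confounds.columns,
    )
    confounds = pd.concat([cohort.confounds, decoy_conf])
    decoy_ph = pd.DataFrame(
        rng.standard_normal((n_decoys, phenome.data.shape[1])),
        index=decoy_frame.index,
        columns=phenome.data.columns,
    )
    ph_all = pd.concat([phenome.data, decoy_ph])

    target_tbl = tcohort.features.data.copy()
    target_tbl.insert(0, "age", tcohort.age)

    write_table(participants, out / "participants.tsv")
    write_table(feats, out / "features.tsv")
    write_table(confounds, out / "confounds.tsv")
    write_table(ph_all, out / "phenome.tsv")
    write_table(target_tbl, out / "target_features.tsv")
    (out / "truth.json").write_text(json.dumps(cohort.truth.to_jsonable(), indent=2))

    config = {
        "out_dir": str(out / "run"),
        "seed": int(seed),
        "n_components": 4,
        "n_perm": 999,
        "n_boot": 200,
        "participants_path": str(out / "participants.tsv"),
        "features_path": str(out / "features.tsv"),
        "confounds_path": str(out / "confounds.tsv"),
        "phenome_path": str(out / "phenome.tsv"),
        "target_features_path": str(out / "target_features.tsv"),
    }
    (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
    return {"out_dir": str(out), "config": str(out / "config.yaml")}
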