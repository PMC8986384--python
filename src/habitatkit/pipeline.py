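"""End-to-end orchestration: simulate -> preprocess -> habitats -> features ->
train -> evaluate, driven by a single validated configuration.

Every stage writes its artifacts under one run directory together with a
machine-readable provenance file (config, seeds, package version), so a run
is fully reproducible from its outputs. All randomness flows from the config
seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .habitats import kmeans_cluster, labels_to_volume
from .model import (
    DEFAULT_MODEL_FEATURES,
    calibration_curve,
    evaluate,
    fit_adaboost_gp,
    roc_auc,
    split_cohort,
)
from .phantom import (
    GroupEffect,
    PhantomParams,
    generate_cohort,
    load_study_nifti,
    save_study_nifti,
)
from .preprocess import SEQUENCE_NAMES, VoxelFeatureMatrix, preprocess_study
from .validity import FEATURE_COLUMNS, compute_all

logger = logging.getLogger("habitatkit")


def _from_dict(cls, d: dict, context: str):
    """Build a dataclass from a dict, rejecting unknown keys."""
    allowed = {f.name for f in fields(cls)}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(
            f"unknown config key(s) in {context}: {', '.join(sorted(unknown))}"
        )
    return cls(**d)


@dataclass(frozen=True)
class SimulateConfig:
    n: int = 40
    prevalence: float = 0.5
    mutant_centroid_scale: float = 1.5
    mutant_dispersion_scale: float = 1.3
    between_subject_sd: float = 0.05
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_radius: float = 8.0
    noise_sd: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_shape", tuple(self.grid_shape))
        object.__setattr__(self, "voxel_spacing", tuple(self.voxel_spacing))

    def effect(self) -> GroupEffect:
        return GroupEffect(
            mutant_centroid_scale=self.mutant_centroid_scale,
            mutant_dispersion_scale=self.mutant_dispersion_scale,
            between_subject_sd=self.between_subject_sd,
        )

    def base_params(self) -> PhantomParams:
        return PhantomParams(
            grid_shape=tuple(self.grid_shape),
            voxel_spacing=tuple(self.voxel_spacing),
            tumor_radius=self.tumor_radius,
            noise_sd=self.noise_sd,
        )


@dataclass(frozen=True)
class PreprocessConfig:
    order: str = "standardize-first"
    smooth: bool = True


@dataclass(frozen=True)
class HabitatsConfig:
    k: int = 3
    n_init: int = 10
    max_iter: int = 300
    tol: float = 1e-6


@dataclass(frozen=True)
class ModelConfig:
    features: tuple[str, ...] = DEFAULT_MODEL_FEATURES
    n_rounds: int = 10
    weak_learner: str = "gp"
    split_ratio: float = 0.8
    threshold: float = 0.5
    n_boot: int = 2000

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple(self.features))


@dataclass(frozen=True)
class RunConfig:
    """Union of per-stage configs; validated before any stage runs."""

    seed: int = 0
    out_dir: str = "runs"
    run_name: str | None = None
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    habitats: HabitatsConfig = field(default_factory=HabitatsConfig)
    model: ModelConfig = field(default_factory=ModelConfig)

    def validate(self) -> None:
        if self.simulate.n < 2:
            raise ValueError("simulate.n must be >= 2")
        if not (0.0 < self.simulate.prevalence < 1.0):
            raise ValueError("simulate.prevalence must be in (0, 1)")
        if self.preprocess.order not in ("standardize-first", "smooth-first"):
            raise ValueError(f"invalid preprocess.order {self.preprocess.order!r}")
        if self.habitats.k < 2:
            raise ValueError(
                "habitats.k must be >= 2 (validity statistics are undefined at k=1)"
            )
        if self.model.weak_learner not in ("gp", "stump"):
            raise ValueError(f"invalid model.weak_learner {self.model.weak_learner!r}")
        if len(self.model.features) != 2:
            raise ValueError("model.features must name exactly two columns")
        unknown = set(self.model.features) - set(FEATURE_COLUMNS)
        if unknown:
            raise ValueError(f"unknown model feature(s): {', '.join(sorted(unknown))}")
        if not (0.0 < self.model.split_ratio < 1.0):
            raise ValueError("model.split_ratio must be in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sections = {}
        for name, sub_cls in (
            ("simulate", SimulateConfig),
            ("preprocess", PreprocessConfig),
            ("habitats", HabitatsConfig),
            ("model", ModelConfig),
        ):
            if name in d:
                sections[name] = _from_dict(sub_cls, d.pop(name), name)
        cfg = _from_dict(cls, {**d, **sections}, "run config")
        cfg.validate()
        return cfg

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage(name: str, study_id: str = "-"):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            elapsed = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage=%s study=%s elapsed=%.2fs", name, study_id, elapsed)
            else:
                logger.error(
                    "stage=%s study=%s failed after %.2fs: %s",
                    name, study_id, elapsed, exc,
                )
            return False

    return _Timer()


def stage_simulate(config: RunConfig, run_dir: Path) -> pd.DataFrame:
    """Generate the phantom cohort and write NIfTI studies plus a manifest."""
    sim = config.simulate
    out = run_dir / "studies"
    rows = []
    with _stage("simulate"):
        cohort = generate_cohort(
            sim.n,
            sim.prevalence,
            effect=sim.effect(),
            seed=config.seed,
            base_params=sim.base_params(),
        )
        for study, truth in cohort:
            paths = save_study_nifti(study, truth, out)
            rows.append(
                {
                    "study_id": study.study_id,
                    "group": truth.group_label,
                    "ihc_percent": truth.ihc_percent,
                    **paths,
                }
            )
    manifest = pd.DataFrame(rows)
    if manifest["study_id"].duplicated().any():
        raise ValueError("duplicate study_ids in the generated cohort")
    manifest.to_csv(run_dir / "manifest.csv", index=False)
    (run_dir / "simulate_params.json").write_text(
        json.dumps(dataclasses.asdict(sim), indent=2, sort_keys=True)
    )
    return manifest


def load_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    if manifest["study_id"].duplicated().any():
        raise ValueError("manifest contains duplicate study_ids")
    for _, row in manifest.iterrows():
        for col in (*SEQUENCE_NAMES, "mask"):
            if not Path(row[col]).exists():
                raise FileNotFoundError(f"{row['study_id']}: missing file {row[col]}")
    return manifest


def stage_preprocess(
    config: RunConfig, run_dir: Path, manifest: pd.DataFrame
) -> dict[str, VoxelFeatureMatrix]:
    """Register/standardize/smooth each study and store its feature matrix."""
    out = run_dir / "preproc"
    out.mkdir(parents=True, exist_ok=True)
    matrices: dict[str, VoxelFeatureMatrix] = {}
    for _, row in manifest.iterrows():
        sid = row["study_id"]
        with _stage("preprocess", sid):
            study = load_study_nifti(row.to_dict(), sid)
            _, fm = preprocess_study(
                study,
                order=config.preprocess.order,
                smooth=config.preprocess.smooth,
            )
            np.savez(out / f"{sid}_features.npz",
                     features=fm.features, voxel_index=fm.voxel_index)
            matrices[sid] = fm
    return matrices


def stage_habitats(
    config: RunConfig,
    run_dir: Path,
    manifest: pd.DataFrame,
    matrices: dict[str, VoxelFeatureMatrix],
) -> dict[str, object]:
    """Cluster each study into K habitats; write label volumes and reports."""
    import nibabel as nib

    out = run_dir / "habitats"
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1)
    labelings: dict[str, object] = {}
    for _, row in manifest.iterrows():
        sid = row["study_id"]
        with _stage("habitats", sid):
            fm = matrices[sid]
            study_seed = int(rng.integers(2**31 - 1))
            labeling = kmeans_cluster(
                fm,
                k=config.habitats.k,
                seed=study_seed,
                max_iter=config.habitats.max_iter,
                tol=config.habitats.tol,
                n_init=config.habitats.n_init,
            )
            labelings[sid] = labeling
            study = load_study_nifti(row.to_dict(), sid)
            vol = labels_to_volume(labeling, study)
            affine = np.diag(list(vol.spacing) + [1.0])
            affine[:3, 3] = vol.origin
            nib.save(
                nib.Nifti1Image(vol.values.astype(np.int16), affine),
                out / f"{sid}_habitats.nii.gz",
            )
            report = {
                "study_id": sid,
                "seed": labeling.seed,
                "n_iter": labeling.n_iter,
                "inertia_trace": labeling.inertia_trace.tolist(),
            }
            (out / f"{sid}_report.json").write_text(json.dumps(report, indent=2))
    return labelings


def stage_features(
    run_dir: Path,
    manifest: pd.DataFrame,
    matrices: dict[str, VoxelFeatureMatrix],
    labelings: dict[str, object],
) -> pd.DataFrame:
    """Validity statistics per study -> the cohort feature table."""
    rows = []
    for _, row in manifest.iterrows():
        sid = row["study_id"]
        with _stage("features", sid):
            vf = compute_all(matrices[sid], labelings[sid], study_id=sid)
            rows.append({**vf.as_dict(), "label": int(row["group"])})
    table = pd.DataFrame(rows)
    table.to_csv(run_dir / "features.csv", index=False)
    return table


def stage_train_evaluate(
    config: RunConfig, run_dir: Path, features: pd.DataFrame
) -> dict:
    """Split, evaluate single features by ROC, fit AdaBoost, evaluate held out."""
    mc = config.model
    usable = features[~features["degenerate"]].reset_index(drop=True)
    with _stage("train"):
        train, test = split_cohort(usable, ratio=mc.split_ratio, seed=config.seed)
        single = {}
        for col in FEATURE_COLUMNS:
            roc = roc_auc(
                train[col].to_numpy(),
                train["label"].to_numpy(),
                n_boot=mc.n_boot,
                seed=config.seed,
            )
            single[col] = {
                "auc": roc.auc, "ci_low": roc.ci_low, "ci_high": roc.ci_high,
                "flipped": roc.flipped,
            }
        model = fit_adaboost_gp(
            train[list(mc.features)].to_numpy(),
            train["label"].to_numpy(),
            n_rounds=mc.n_rounds,
            seed=config.seed,
            weak_learner=mc.weak_learner,
            feature_names=mc.features,
        )
        model.to_json(run_dir / "model.json")
    with _stage("evaluate"):
        results = {}
        for name, part in (("train", train), ("test", test)):
            roc, at_thr, at_youden = evaluate(
                model,
                part[list(mc.features)].to_numpy(),
                part["label"].to_numpy(),
                threshold=mc.threshold,
                n_boot=mc.n_boot,
                seed=config.seed,
            )
            pd.DataFrame(
                {
                    "threshold": roc.thresholds,
                    "sensitivity": roc.sensitivities,
                    "specificity": roc.specificities,
                }
            ).to_csv(run_dir / f"roc_{name}.csv", index=False)
            probs = model.predict_proba(part[list(mc.features)].to_numpy())
            pred_mean, obs_frac, counts = calibration_curve(
                probs, part["label"].to_numpy()
            )
            pd.DataFrame(
                {"mean_predicted": pred_mean, "observed_fraction": obs_frac,
                 "count": counts}
            ).to_csv(run_dir / f"calibration_{name}.csv", index=False)
            results[name] = {
                "auc": roc.auc, "ci_low": roc.ci_low, "ci_high": roc.ci_high,
                "n_pos": roc.n_pos, "n_neg": roc.n_neg,
                "accuracy": at_thr.accuracy,
                "sensitivity": at_thr.sensitivity,
                "specificity": at_thr.specificity,
                "youden_threshold": at_youden.threshold,
                "youden_accuracy": at_youden.accuracy,
                "youden_sensitivity": at_youden.sensitivity,
                "youden_specificity": at_youden.specificity,
            }
    metrics = {"single_feature_roc": single, "model": results,
               "n_train": len(train), "n_test": len(test),
               "n_excluded_degenerate": int(features["degenerate"].sum())}
    (run_dir / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    return metrics


def save_plots(run_dir: Path) -> None:
    """ROC and calibration figures from the stage CSVs (best effort)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5))
    for name, color in (("train", "C0"), ("test", "C1")):
        roc = pd.read_csv(run_dir / f"roc_{name}.csv")
        axes[0].plot(1 - roc["specificity"], roc["sensitivity"],
                     color=color, label=name)
        cal = pd.read_csv(run_dir / f"calibration_{name}.csv")
        axes[1].plot(cal["mean_predicted"], cal["observed_fraction"],
                     "o-", color=color, label=name)
    axes[0].plot([0, 1], [0, 1], "k--", lw=0.8)
    axes[0].set(xlabel="1 - specificity", ylabel="sensitivity", title="ROC")
    axes[1].plot([0, 1], [0, 1], "k--", lw=0.8)
    axes[1].set(xlabel="mean predicted probability",
                ylabel="observed fraction", title="Calibration")
    for ax in axes:
        ax.legend()
    fig.tight_layout()
    fig.savefig(run_dir / "summary.png", dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage under a fresh run directory; returns that directory."""
    config.validate()
    stamp = config.run_name or time.strftime("run-%Y%m%d-%H%M%S")
    run_dir = Path(config.out_dir) / stamp
    run_dir.mkdir(parents=True, exist_ok=True)

    cfg_dict = config.to_dict()
    cfg_text = json.dumps(cfg_dict, indent=2, sort_keys=True)
    provenance = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": config.seed,
        "habitatkit_version": __version__,
    }
    (run_dir / "provenance.json").write_text(json.dumps(provenance, indent=2,
                                                        sort_keys=True))

    manifest = stage_simulate(config, run_dir)
    matrices = stage_preprocess(config, run_dir, manifest)
    labelings = stage_habitats(config, run_dir, manifest, matrices)
    features = stage_features(run_dir, manifest, matrices, labelings)
    stage_train_evaluate(config, run_dir, features)
    save_plots(run_dir)
    logger.info("pipeline complete: %s", run_dir)
    return run_dir
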