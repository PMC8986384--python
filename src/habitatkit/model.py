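"""Mutation-status prediction from cluster-validity features.

Two evaluation routes mirror the analysis design:

* single features are scored by ROC analysis — the AUC is the normalized
  Mann-Whitney U statistic (tied score pairs count 1/2), with a stratified
  percentile-bootstrap confidence interval; biomarker direction is
  auto-oriented so the reported AUC is >= 0.5 unless disabled;
* the two-feature joint model is discrete AdaBoost (two-class SAMME) whose
  weak classifier is a Gaussian-process classifier with an RBF kernel on
  train-standardized features. GP classifiers do not accept sample weights,
  so each round fits on a weight-proportional bootstrap resample — the
  standard recipe for unweightable weak learners. A decision-stump weak
  learner (fit directly on the weights) is available by flag and makes the
  boosting arithmetic exactly traceable.

Operating metrics (accuracy / sensitivity / specificity) are reported at a
probability threshold (default 0.5) and at the Youden-optimal point, and a
reliability (calibration) curve summarizes probability quality.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF, ConstantKernel
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import train_test_split

logger = logging.getLogger("habitatkit")

#: The two validity features used by the joint model.
DEFAULT_MODEL_FEATURES = ("calinski_harabasz", "inertia")


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    n_pos: int
    n_neg: int
    flipped: bool = False  # True when the score direction was inverted


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U; tied pairs count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores)  # average ranks handle ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    orient: bool = True,
) -> RocResult:
    """ROC curve, AUC and stratified percentile-bootstrap 95% CI.

    With ``orient=True`` (the single-biomarker setting) the score sign is
    flipped whenever the raw AUC is below 0.5, and the flip is recorded in
    ``flipped``; model probability scores should pass ``orient=False``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc = mann_whitney_auc(scores, labels)
    flipped = False
    if orient and auc < 0.5:
        scores = -scores
        auc = 1.0 - auc
        flipped = True
        logger.debug("roc_auc: score direction inverted (raw AUC below 0.5)")

    fpr, tpr, thr = _sk_roc_curve(labels, scores)

    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        p = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        q = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        idx = np.concatenate([p, q])
        boot[b] = mann_whitney_auc(scores[idx], labels[idx])
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5])
    return RocResult(
        auc=auc,
        ci_low=float(min(ci_low, auc)),
        ci_high=float(max(ci_high, auc)),
        thresholds=thr,
        sensitivities=tpr,
        specificities=1.0 - fpr,
        n_pos=int(labels.sum()),
        n_neg=int(len(labels) - labels.sum()),
        flipped=flipped,
    )


# ---------------------------------------------------------------------------
# Cohort split
# ---------------------------------------------------------------------------

def split_cohort(
    features: pd.DataFrame,
    ratio: float = 0.8,
    seed: int = 0,
    label_column: str = "label",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split (default 0.8, mirroring a 100:25 design)."""
    labels = features[label_column].to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present before splitting")
    train, test = train_test_split(
        features,
        train_size=ratio,
        stratify=labels,
        random_state=seed,
        shuffle=True,
    )
    for part, name in ((train, "train"), (test, "test")):
        if len(np.unique(part[label_column])) < 2:
            raise ValueError(f"class absent from the {name} split")
    return train.reset_index(drop=True), test.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Weak learners
# ---------------------------------------------------------------------------

@dataclass
class DecisionStump:
    """Axis-aligned threshold classifier fit by exhaustive weighted search.

    ``polarity=+1`` predicts class 1 for ``x[feature] > threshold``;
    ``polarity=-1`` predicts class 1 for ``x[feature] <= threshold``.
    Ties in weighted error resolve to the first candidate in scan order
    (feature, then threshold, then polarity +1 before -1), which keeps the
    fit fully deterministic.
    """

    feature: int = 0
    threshold: float = 0.0
    polarity: int = 1

    def fit(self, X: np.ndarray, y: np.ndarray, w: np.ndarray) -> "DecisionStump":
        best_err = np.inf
        for f in range(X.shape[1]):
            xs = X[:, f]
            cuts = np.unique(xs)
            midpoints = (cuts[:-1] + cuts[1:]) / 2.0
            candidates = np.concatenate(([cuts[0] - 1.0], midpoints))
            for t in candidates:
                for pol in (1, -1):
                    pred = self._predict_raw(xs, t, pol)
                    err = float(w[pred != y].sum())
                    if err < best_err - 1e-15:
                        best_err = err
                        self.feature, self.threshold, self.polarity = f, float(t), pol
        return self

    @staticmethod
    def _predict_raw(xs: np.ndarray, t: float, pol: int) -> np.ndarray:
        return ((xs > t) if pol == 1 else (xs <= t)).astype(int)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._predict_raw(X[:, self.feature], self.threshold, self.polarity)

    def to_dict(self) -> dict:
        return {
            "type": "stump",
            "feature": self.feature,
            "threshold": self.threshold,
            "polarity": self.polarity,
        }


class GPWeakLearner:
    """Gaussian-process weak classifier fit on a bootstrap resample.

    The RBF length scale is fixed at 1.0 on standardized features rather than
    optimized: per-round marginal-likelihood fitting on a weight-biased
    resample drives the scale toward zero and lets the GP memorize the
    resample, which defeats its role as a weak (smooth, slightly-better-
    than-chance) classifier and makes the ensemble generalize poorly.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, seed: int):
        kernel = ConstantKernel(1.0) * RBF(length_scale=1.0)
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        self.seed = int(seed)
        self.clf = GaussianProcessClassifier(
            kernel=kernel, optimizer=None, random_state=self.seed
        )
        self.clf.fit(self.X, self.y)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.clf.predict(X).astype(int)

    def to_dict(self) -> dict:
        return {
            "type": "gp",
            "seed": self.seed,
            "kernel_theta": self.clf.kernel_.theta.tolist(),
            "X": self.X.tolist(),
            "y": self.y.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GPWeakLearner":
        obj = cls.__new__(cls)
        obj.X = np.asarray(d["X"], dtype=float)
        obj.y = np.asarray(d["y"], dtype=int)
        obj.seed = int(d["seed"])
        kernel = ConstantKernel(1.0) * RBF(length_scale=1.0)
        kernel.theta = np.asarray(d["kernel_theta"])
        # Refit with the stored optimized kernel frozen: deterministic rebuild.
        obj.clf = GaussianProcessClassifier(
            kernel=kernel, optimizer=None, random_state=obj.seed
        )
        obj.clf.fit(obj.X, obj.y)
        return obj


# ---------------------------------------------------------------------------
# AdaBoost
# ---------------------------------------------------------------------------

@dataclass
class BoostRound:
    learner: object
    alpha: float
    error: float


@dataclass
class BoostedModel:
    """Discrete AdaBoost ensemble over standardized features."""

    rounds: list[BoostRound]
    feature_names: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    weak_learner: str
    seed: int
    weight_history: list[np.ndarray] = field(default_factory=list)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Weighted vote margin ``sum_t alpha_t h_t(x)`` with h in {-1,+1}."""
        Xs = self._standardize(X)
        F = np.zeros(Xs.shape[0])
        for r in self.rounds:
            h = r.learner.predict(Xs) * 2 - 1
            F += r.alpha * h
        return F

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Sigmoid-calibrated vote: P(class 1) = logistic(2 * margin)."""
        return 1.0 / (1.0 + np.exp(-2.0 * self.decision_function(X)))

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "feature_names": list(self.feature_names),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "weak_learner": self.weak_learner,
            "seed": self.seed,
            "rounds": [
                {"alpha": r.alpha, "error": r.error, "learner": r.learner.to_dict()}
                for r in self.rounds
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "BoostedModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        rounds = []
        for r in d["rounds"]:
            spec = r["learner"]
            if spec["type"] == "stump":
                learner: object = DecisionStump(
                    feature=spec["feature"],
                    threshold=spec["threshold"],
                    polarity=spec["polarity"],
                )
            elif spec["type"] == "gp":
                learner = GPWeakLearner.from_dict(spec)
            else:
                raise ValueError(f"unknown weak learner type {spec['type']!r}")
            rounds.append(BoostRound(learner, float(r["alpha"]), float(r["error"])))
        return cls(
            rounds=rounds,
            feature_names=tuple(d["feature_names"]),
            mean=np.asarray(d["mean"], dtype=float),
            sd=np.asarray(d["sd"], dtype=float),
            weak_learner=d["weak_learner"],
            seed=int(d["seed"]),
        )


def fit_adaboost_gp(
    X: np.ndarray,
    y: np.ndarray,
    n_rounds: int = 10,
    seed: int = 0,
    weak_learner: str = "gp",
    feature_names: Sequence[str] = DEFAULT_MODEL_FEATURES,
) -> BoostedModel:
    """Fit the two-feature boosted model.

    Per round the weak learner is fit (GP: on a weight-proportional bootstrap
    resample; stump: directly on the weights), its weighted training error
    ``eps`` computed on the full set, and its vote weight set to
    ``alpha = 0.5 * ln((1 - eps)/eps)``. Rounds with ``eps >= 0.5`` are
    rejected and stop the boosting; ``eps = 0`` keeps the round with a capped
    alpha and stops (a perfect learner). Sample weights update by the
    standard ``w <- w * exp(-alpha * y_pm * h_pm)`` rule and renormalize.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] < 8:
        raise ValueError("need at least 8 training samples")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in training data")
    if weak_learner not in ("gp", "stump"):
        raise ValueError(f"unknown weak learner {weak_learner!r}")

    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xs = (X - mean) / sd

    rng = np.random.default_rng(seed)
    n = X.shape[0]
    w = np.full(n, 1.0 / n)
    y_pm = y * 2 - 1

    rounds: list[BoostRound] = []
    weight_history: list[np.ndarray] = [w.copy()]
    for t in range(n_rounds):
        if weak_learner == "stump":
            learner: object = DecisionStump().fit(Xs, y, w)
        else:
            learner = None
            for _ in range(20):  # resample until both classes are present
                idx = rng.choice(n, size=n, replace=True, p=w)
                if len(np.unique(y[idx])) == 2:
                    learner = GPWeakLearner(
                        Xs[idx], y[idx], seed=int(rng.integers(2**31 - 1))
                    )
                    break
            if learner is None:
                break  # weights collapsed onto one class; stop boosting
        pred = learner.predict(Xs)
        eps = float(w[pred != y].sum())
        if eps >= 0.5:
            if not rounds:
                raise ValueError(
                    "every weak learner was rejected (weighted error >= 0.5); "
                    "try weak_learner='stump'"
                )
            break
        if eps == 0.0:
            alpha = 0.5 * math.log((1.0 - 1e-10) / 1e-10)
            rounds.append(BoostRound(learner, alpha, eps))
            break
        alpha = 0.5 * math.log((1.0 - eps) / eps)
        rounds.append(BoostRound(learner, alpha, eps))
        h_pm = pred * 2 - 1
        w = w * np.exp(-alpha * y_pm * h_pm)
        w = w / w.sum()
        weight_history.append(w.copy())

    if not rounds:
        raise ValueError(
            "boosting produced no usable round; try weak_learner='stump'"
        )
    logger.debug(
        "adaboost(%s): %d rounds, final eps=%.4f", weak_learner,
        len(rounds), rounds[-1].error,
    )
    return BoostedModel(
        rounds=rounds,
        feature_names=tuple(feature_names),
        mean=mean,
        sd=sd,
        weak_learner=weak_learner,
        seed=seed,
        weight_history=weight_history,
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class OperatingMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    threshold: float


def operating_metrics(
    probs: np.ndarray, labels: np.ndarray, threshold: float
) -> OperatingMetrics:
    """Confusion-matrix summary at one probability threshold."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = (probs >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    return OperatingMetrics(
        accuracy=(tp + tn) / len(labels),
        sensitivity=tp / (tp + fn) if (tp + fn) else 0.0,
        specificity=tn / (tn + fp) if (tn + fp) else 0.0,
        threshold=float(threshold),
    )


def evaluate(
    model: BoostedModel,
    X: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[RocResult, OperatingMetrics, OperatingMetrics]:
    """Score a fitted model on a dataset.

    Returns the ROC of the predicted probabilities (direction fixed, no
    auto-orientation), the operating metrics at ``threshold``, and the
    operating metrics at the Youden-optimal (max sensitivity+specificity-1)
    threshold.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("evaluation set must contain both classes")
    probs = model.predict_proba(X)
    roc = roc_auc(probs, labels, n_boot=n_boot, seed=seed, orient=False)
    at_threshold = operating_metrics(probs, labels, threshold)
    youden = roc.sensitivities + roc.specificities - 1.0
    youden_thr = float(np.clip(roc.thresholds[int(np.argmax(youden))], 0.0, 1.0))
    at_youden = operating_metrics(probs, labels, youden_thr)
    return roc, at_threshold, at_youden


def calibration_curve(
    probs: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reliability curve on equal-width probability bins.

    Returns per nonempty bin: mean predicted probability, observed positive
    fraction, and sample count. The final bin includes 1.0.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bin_idx = np.clip(np.digitize(probs, edges[1:-1], right=False), 0, n_bins - 1)
    pred_mean, obs_frac, counts = [], [], []
    for b in range(n_bins):
        sel = bin_idx == b
        if not sel.any():
            continue
        pred_mean.append(float(probs[sel].mean()))
        obs_frac.append(float(labels[sel].mean()))
        counts.append(int(sel.sum()))
    return np.asarray(pred_mean), np.asarray(obs_frac), np.asarray(counts)
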