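"""The six classifier families, their search spaces, and TPE-based tuning.

Families: SVM (RBF kernel), LDA, random forest (RF), extremely randomized
trees (ET), and two gradient-boosting implementations — LightGBM and
scikit-learn's histogram gradient boosting (family key "GB").  Every family
exposes calibrated class probabilities; hard labels are probability >= 0.5.

Hyperparameters are optimized by maximizing mean stratified-CV Matthews
correlation with the package's tree-structured Parzen estimator sampler
(:mod:`antiangio.tpe`), with median-rule pruning after the first three folds.
The quartile scaler is re-fit on each training fold, never on held-out data.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (ExtraTreesClassifier,
                              HistGradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .preprocess import QuartileScaler, fit_quartile_scaler
from .tpe import Categorical, Int, Real, TPESampler

FAMILIES = ("SVM", "LDA", "RF", "ET", "LightGBM", "GB")

# Declared search spaces per family (tuning never leaves these bounds).
SEARCH_SPACES: dict[str, list] = {
    "SVM": [Real("C", 1e-2, 1e3, log=True), Real("gamma", 1e-4, 1e1, log=True)],
    "LDA": [Categorical("use_shrinkage", (False, True)),
            Real("shrinkage_value", 0.0, 1.0)],
    "RF": [Int("n_estimators", 100, 1000), Int("max_depth", 2, 16),
           Int("min_samples_leaf", 1, 8)],
    "ET": [Int("n_estimators", 100, 1000), Int("max_depth", 2, 16),
           Int("min_samples_leaf", 1, 8)],
    "LightGBM": [Real("learning_rate", 1e-3, 0.3, log=True),
                 Int("num_leaves", 2, 64), Int("n_estimators", 100, 1000),
                 Int("min_child_samples", 2, 30)],
    "GB": [Real("learning_rate", 1e-3, 0.3, log=True),
           Int("max_depth", 2, 16), Int("max_iter", 100, 1000),
           Int("min_samples_leaf", 2, 30)],
}


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family plus concrete hyperparameters and a seed."""

    family: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; "
                             f"choose from {FAMILIES}")
        known = {p.name for p in SEARCH_SPACES[self.family]}
        unknown = set(self.params) - known
        if unknown:
            raise ValueError(f"{self.family}: unknown hyperparameter(s) {sorted(unknown)}")


def make_default_model(family: str, seed: int = 0) -> ModelSpec:
    """Library-default hyperparameters for a family (SVM uses the RBF kernel)."""
    return ModelSpec(family, {}, seed)


def build_estimator(spec: ModelSpec):
    """Instantiate the scikit-learn / LightGBM estimator for a spec.

    All estimators output class probabilities; randomness is pinned to the
    spec seed and computation to one thread for reproducibility.
    """
    f, p, seed = spec.family, dict(spec.params), spec.seed
    if f == "SVM":
        return SVC(kernel="rbf", probability=True, random_state=seed,
                   C=p.get("C", 1.0), gamma=p.get("gamma", "scale"))
    if f == "LDA":
        if p.get("use_shrinkage", False):
            return LinearDiscriminantAnalysis(
                solver="lsqr", shrinkage=p.get("shrinkage_value", "auto"))
        return LinearDiscriminantAnalysis()
    if f == "RF":
        return RandomForestClassifier(
            random_state=seed, n_jobs=1,
            n_estimators=p.get("n_estimators", 100),
            max_depth=p.get("max_depth", None),
            min_samples_leaf=p.get("min_samples_leaf", 1))
    if f == "ET":
        return ExtraTreesClassifier(
            random_state=seed, n_jobs=1,
            n_estimators=p.get("n_estimators", 100),
            max_depth=p.get("max_depth", None),
            min_samples_leaf=p.get("min_samples_leaf", 1))
    if f == "LightGBM":
        return LGBMClassifier(
            random_state=seed, n_jobs=1, verbose=-1,
            learning_rate=p.get("learning_rate", 0.1),
            num_leaves=p.get("num_leaves", 31),
            n_estimators=p.get("n_estimators", 100),
            min_child_samples=p.get("min_child_samples", 20))
    if f == "GB":
        return HistGradientBoostingClassifier(
            random_state=seed,
            learning_rate=p.get("learning_rate", 0.1),
            max_depth=p.get("max_depth", None),
            max_iter=p.get("max_iter", 100),
            min_samples_leaf=p.get("min_samples_leaf", 20))
    raise ValueError(f"unknown family {f!r}")  # pragma: no cover


def _cv_mcc(X: pd.DataFrame, y: np.ndarray, spec: ModelSpec, cv_folds: int,
            seed: int, stop_after: int | None = None,
            prune_below: float | None = None) -> tuple[float, list[float]]:
    """Mean fold MCC with per-fold scaler refit; optional median-rule pruning.

    If ``prune_below`` is given, the trial is abandoned (returns NaN) when the
    mean of the first ``stop_after`` folds falls below it.
    """
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    scores: list[float] = []
    for fold, (tr, te) in enumerate(skf.split(X, y), 1):
        scaler = fit_quartile_scaler(X.iloc[tr])
        est = build_estimator(spec)
        est.fit(scaler.transform(X.iloc[tr]).to_numpy(), y[tr])
        pred = est.predict(scaler.transform(X.iloc[te]).to_numpy())
        scores.append(matthews_corrcoef(y[te], pred))
        if (stop_after is not None and fold == stop_after
                and prune_below is not None
                and float(np.mean(scores)) < prune_below):
            return float("nan"), scores
    return float(np.mean(scores)), scores


@dataclass
class TuneResult:
    family: str
    best_params: dict
    best_score: float
    trials: pd.DataFrame  # columns: trial, score, status, params (JSON)
    n_trials: int
    seed: int


def tune_hyperparameters(X: pd.DataFrame, y, family: str,
                         space: Sequence | None = None, n_trials: int = 100,
                         cv_folds: int = 10, seed: int = 0,
                         pruning: bool = True) -> TuneResult:
    """TPE search maximizing mean stratified-CV MCC; deterministic given seed.

    Unpromising trials are pruned by the median rule after 3 folds (their
    partial scores are logged but excluded from the best).  A trial whose CV
    degenerates (e.g. a single-class fold) is scored failed and excluded.
    """
    y = np.asarray(y, int)
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    space = list(space) if space is not None else SEARCH_SPACES[family]
    sampler = TPESampler(space, seed=seed)
    history: list[tuple[dict, float]] = []
    rows = []
    early_means: list[float] = []
    for t in range(n_trials):
        params = sampler.suggest(history)
        spec = ModelSpec(family, params, seed)
        prune_at = float(np.median(early_means)) if (pruning and early_means) else None
        try:
            score, folds = _cv_mcc(X, y, spec, cv_folds, seed,
                                   stop_after=3 if pruning else None,
                                   prune_below=prune_at)
            status = "pruned" if np.isnan(score) else "complete"
        except ValueError:
            score, folds, status = float("nan"), [], "failed"
        if len(folds) >= 3:
            early_means.append(float(np.mean(folds[:3])))
        if status == "complete":
            history.append((params, score))
        rows.append({"trial": t, "score": score, "status": status,
                     "params": json.dumps(params, sort_keys=True)})
    trials = pd.DataFrame(rows)
    done = trials[trials.status == "complete"]
    if done.empty:
        raise RuntimeError("no trial completed; check the data or space")
    best = done.loc[done.score.idxmax()]
    return TuneResult(family, json.loads(best.params), float(best.score),
                      trials, n_trials, seed)


@dataclass
class TrainedModel:
    """A fitted classifier plus its training-set scaler and feature order."""

    spec: ModelSpec
    scaler: QuartileScaler
    estimator: object
    feature_names: tuple[str, ...]
    threshold: float = 0.5

    def predict_proba(self, m: pd.DataFrame) -> np.ndarray:
        """Probability of the positive class for each row."""
        Xs = self.scaler.transform(m[list(self.feature_names)])
        proba = self.estimator.predict_proba(Xs.to_numpy())
        pos_col = list(self.estimator.classes_).index(1)
        return proba[:, pos_col]

    def predict(self, m: pd.DataFrame) -> np.ndarray:
        """Hard labels: 1 iff positive-class probability >= threshold."""
        return (self.predict_proba(m) >= self.threshold).astype(int)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        sidecar = {"family": self.spec.family, "params": self.spec.params,
                   "seed": self.spec.seed, "threshold": self.threshold,
                   "n_features": len(self.feature_names)}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2))

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def fit_final(m: pd.DataFrame, labels, spec: ModelSpec) -> TrainedModel:
    """Fit on the complete development matrix (scaler fit on the same data).

    This is the retrain-before-independent-test step: the final model sees
    all development samples, including the fold held out during CV.
    """
    y = np.asarray(labels, int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    scaler = fit_quartile_scaler(m)
    est = build_estimator(spec)
    est.fit(scaler.transform(m).to_numpy(), y)
    return TrainedModel(spec, scaler, est, tuple(m.columns))
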