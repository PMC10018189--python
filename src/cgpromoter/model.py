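"""Random-forest training with grid search under stratified k-fold CV.

The classifier is a Gini-criterion random forest. Hyperparameters are
tuned by exhaustive grid search over five axes — number of trees 80..150
step 5, depth 15..20, min samples per leaf 1..8, min samples per split
2..5, and the fraction of features tried per split 0.1..1.0 step 0.1 —
28,800 combinations in all, each scored by its mean objective (accuracy by
default) over stratified five-fold cross-validation. Every random choice
(fold assignment, forest bootstrap) is seeded so a search is reproducible.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .encoder import FeatureMatrix

logger = logging.getLogger("cgpromoter")


def _inclusive_range(lo: int, hi: int, step: int) -> tuple[int, ...]:
    return tuple(range(lo, hi + 1, step))


@dataclass
class RFGrid:
    """Hyperparameter grid; defaults are the full published search ranges."""

    n_estimators: tuple[int, ...] = _inclusive_range(80, 150, 5)
    max_depth: tuple[int, ...] = _inclusive_range(15, 20, 1)
    min_samples_leaf: tuple[int, ...] = _inclusive_range(1, 8, 1)
    min_samples_split: tuple[int, ...] = _inclusive_range(2, 5, 1)
    max_features_fraction: tuple[float, ...] = tuple(
        round(0.1 * i, 1) for i in range(1, 11)
    )

    def __len__(self) -> int:
        return (
            len(self.n_estimators) * len(self.max_depth)
            * len(self.min_samples_leaf) * len(self.min_samples_split)
            * len(self.max_features_fraction)
        )

    def combinations(self):
        """All parameter dicts in canonical (tie-break) order."""
        for ne, md, msl, mss, mf in itertools.product(
            self.n_estimators, self.max_depth, self.min_samples_leaf,
            self.min_samples_split, self.max_features_fraction,
        ):
            yield {
                "n_estimators": ne, "max_depth": md,
                "min_samples_leaf": msl, "min_samples_split": mss,
                "max_features_fraction": mf,
            }

    def contains(self, params: dict) -> bool:
        return (
            params["n_estimators"] in self.n_estimators
            and params["max_depth"] in self.max_depth
            and params["min_samples_leaf"] in self.min_samples_leaf
            and params["min_samples_split"] in self.min_samples_split
            and any(
                math.isclose(params["max_features_fraction"], f)
                for f in self.max_features_fraction
            )
        )

    @classmethod
    def reduced(cls) -> "RFGrid":
        """A small grid for smoke runs and CI-scale searches."""
        return cls(
            n_estimators=(80, 100),
            max_depth=(15,),
            min_samples_leaf=(1,),
            min_samples_split=(2,),
            max_features_fraction=(0.3,),
        )


@dataclass
class CVPlan:
    """Stratified fold assignment: folds[i] in 0..k-1 for sample i."""

    folds: np.ndarray
    k: int
    seed: int

    def __post_init__(self) -> None:
        self.folds = np.asarray(self.folds, dtype=int)

    def split(self):
        for f in range(self.k):
            test = np.flatnonzero(self.folds == f)
            train = np.flatnonzero(self.folds != f)
            yield train, test


def make_cv_plan(labels: Sequence[int], k: int = 5, seed: int = 0) -> CVPlan:
    """Assign samples to k stratified folds (per-class sizes differ by <= 1)."""
    y = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise ValueError(f"class {cls} has {len(idx)} samples, fewer than k={k}")
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    return CVPlan(folds=folds, k=k, seed=seed)


def _resolve_max_features(fraction: float, d: int) -> int:
    """Features tried per split: ceil(fraction * d), at least 1."""
    return max(1, math.ceil(fraction * d))


def _build_forest(params: dict, d: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=params["n_estimators"],
        max_depth=params["max_depth"],
        min_samples_leaf=params["min_samples_leaf"],
        min_samples_split=params["min_samples_split"],
        max_features=_resolve_max_features(params["max_features_fraction"], d),
        criterion="gini",
        random_state=seed,
        n_jobs=1,
    )


def _score(objective: str, y_true: np.ndarray, scores: np.ndarray) -> float:
    # local import avoids a circular dependency with evaluation
    from .evaluation import confusion, metrics, roc_auc

    pred = (scores >= 0.5).astype(int)
    if objective == "acc":
        return float((pred == y_true).mean())
    if objective == "mcc":
        return metrics(confusion(y_true, pred)).mcc
    if objective == "auc":
        return roc_auc(y_true, scores).auc
    raise ValueError(f"unknown objective {objective!r}")


def grid_search(
    matrix: FeatureMatrix,
    grid: RFGrid,
    plan: CVPlan,
    objective: str = "acc",
    seed: int = 0,
) -> tuple[dict, list[dict]]:
    """Mean-CV-objective argmax over the grid.

    Each combination trains on k-1 folds and is scored on the held-out
    fold; the mean over folds is its CV score. Single-class evaluation
    folds are skipped with a warning. Ties on the mean score go to the
    earliest combination in canonical order (fewer trees, then shallower
    depth, then lexicographic on the remaining axes), so the search is
    deterministic.

    Returns the best parameter dict and the per-combination records
    (params + per-fold and mean scores).
    """
    if matrix.labels is None:
        raise ValueError("grid search needs a labeled matrix")
    if len(grid) == 0:
        raise ValueError("empty grid")
    y = matrix.labels
    X = matrix.values
    folds = list(plan.split())
    records: list[dict] = []
    best: dict | None = None
    best_score = -np.inf
    for params in grid.combinations():
        fold_scores: list[float] = []
        for train_idx, test_idx in folds:
            if len(np.unique(y[test_idx])) < 2 and objective == "auc":
                logger.warning("skipping single-class fold in grid search")
                continue
            if len(np.unique(y[train_idx])) < 2:
                logger.warning("skipping single-class training fold")
                continue
            forest = _build_forest(params, X.shape[1], seed)
            forest.fit(X[train_idx], y[train_idx])
            scores = _class1_scores(forest, X[test_idx])
            fold_scores.append(_score(objective, y[test_idx], scores))
        mean_score = float(np.mean(fold_scores)) if fold_scores else np.nan
        records.append({**params, "fold_scores": fold_scores, "mean": mean_score})
        if fold_scores and mean_score > best_score:  # strict > keeps first on ties
            best_score = mean_score
            best = dict(params)
    if best is None:
        raise ValueError("no grid combination could be evaluated")
    logger.info("grid search best %s = %.4f at %s", objective, best_score, best)
    return best, records


def _class1_scores(forest: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    proba = forest.predict_proba(X)
    col = int(np.flatnonzero(forest.classes_ == 1)[0])
    return proba[:, col]


@dataclass
class TrainedModel:
    """A fitted forest plus everything needed to reuse it safely."""

    forest: RandomForestClassifier
    params: dict
    feature_ids: list[str]
    seed: int
    cv_seed: int | None = None
    selection_report_hash: str | None = None

    def save(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write <prefix>.joblib (forest) and <prefix>.json (sidecar)."""
        prefix = Path(prefix)
        model_path = prefix.with_suffix(".joblib")
        sidecar_path = prefix.with_suffix(".json")
        joblib.dump(self.forest, model_path)
        sidecar = {
            "format_version": 1,
            "params": self.params,
            "feature_ids": self.feature_ids,
            "seed": self.seed,
            "cv_seed": self.cv_seed,
            "selection_report_hash": self.selection_report_hash,
        }
        sidecar_path.write_text(json.dumps(sidecar, indent=1))
        return model_path, sidecar_path

    @classmethod
    def load(cls, prefix: str | Path) -> "TrainedModel":
        prefix = Path(prefix)
        forest = joblib.load(prefix.with_suffix(".joblib"))
        sidecar = json.loads(prefix.with_suffix(".json").read_text())
        return cls(
            forest=forest,
            params=sidecar["params"],
            feature_ids=sidecar["feature_ids"],
            seed=sidecar["seed"],
            cv_seed=sidecar.get("cv_seed"),
            selection_report_hash=sidecar.get("selection_report_hash"),
        )


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def train_final(
    matrix: FeatureMatrix,
    params: dict,
    seed: int = 0,
    grid: RFGrid | None = None,
    cv_seed: int | None = None,
    selection_report_hash: str | None = None,
) -> TrainedModel:
    """Fit the final forest on the full training matrix with given params.

    If a grid is supplied, the params must lie inside its domain.
    """
    if matrix.labels is None:
        raise ValueError("training needs a labeled matrix")
    if grid is not None and not grid.contains(params):
        raise ValueError(f"params {params} outside the grid domain")
    forest = _build_forest(params, matrix.n_features, seed)
    forest.fit(matrix.values, matrix.labels)
    return TrainedModel(
        forest=forest, params=dict(params), feature_ids=list(matrix.feature_ids),
        seed=seed, cv_seed=cv_seed, selection_report_hash=selection_report_hash,
    )


def predict(model: TrainedModel, matrix: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and class-1 scores for a feature matrix.

    The matrix must carry exactly the training feature ids; a column
    permutation with matching ids is realigned automatically, anything
    else is rejected. The score is the fraction of trees voting class 1;
    label = 1 iff score >= 0.5.
    """
    if matrix.feature_ids != model.feature_ids:
        if sorted(matrix.feature_ids) == sorted(model.feature_ids):
            order = [matrix.feature_ids.index(f) for f in model.feature_ids]
            X = matrix.values[:, order]
            logger.info("realigned %d permuted feature columns", len(order))
        else:
            raise ValueError("feature_ids do not match the training features")
    else:
        X = matrix.values
    scores = _class1_scores(model.forest, X)
    labels = (scores >= 0.5).astype(int)
    return labels, scores
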