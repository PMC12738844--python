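"""Tree-ensemble attribute models for building use type and floor count.

Use type is an 8-class random-forest classification; the per-building
probability vector is the fraction of trees voting for each class, so every
probability is a multiple of 1/T and the vector sums to exactly 1.  Floor
count uses a random-forest *regressor* whose per-tree continuous outputs are
rounded to the nearest integer (round-half-to-even) and clamped to >= 1;
tallying the rounded per-tree values gives a discrete distribution.  The
regression route exists because floor-count label data rarely cover every
class, which rules out a direct classifier.

A per-building joint distribution over (use type, floor count) is formed as
the normalized outer product of the two marginals, and floors are sampled
conditionally on the drawn use type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import classification_report, f1_score, mean_absolute_error
from sklearn.model_selection import GridSearchCV, train_test_split

#: The eight broad use-type categories, in canonical order.
USE_TYPES: tuple[str, ...] = (
    "Residential", "Institutional", "Retail", "Commercial",
    "Transportation", "Military", "Recreation", "Agriculture",
)

#: Exhaustive hyperparameter grid: 5 x 4 x 4 = 80 candidate settings.
DEFAULT_GRID: dict[str, list] = {
    "max_depth": [10, 20, 30, 40, None],
    "min_samples_split": [2, 5, 10, 20],
    "min_samples_leaf": [1, 2, 5, 10],
}

#: Small grid for quick runs (tests, demos); 2 x 1 x 2 = 4 settings.
REDUCED_GRID: dict[str, list] = {
    "max_depth": [20, None],
    "min_samples_split": [2],
    "min_samples_leaf": [1, 5],
}


@dataclass
class UseTypeDistribution:
    """Categorical distribution over the eight use types."""

    probs: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"use-type probabilities sum to {total}, not 1")
        if any(p < 0 or p > 1 for p in self.probs.values()):
            raise ValueError("probabilities must lie in [0, 1]")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        labels = np.array(list(self.probs.keys()), dtype=object)
        p = np.array(list(self.probs.values()), dtype=float)
        return labels, p


@dataclass
class FloorDistribution:
    """Discrete distribution over integer floor counts (>= 1)."""

    probs: dict[int, float]

    def __post_init__(self) -> None:
        if any(f < 1 for f in self.probs):
            raise ValueError("floor counts must be >= 1")
        total = sum(self.probs.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"floor probabilities sum to {total}, not 1")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        floors = np.array(sorted(self.probs), dtype=int)
        p = np.array([self.probs[f] for f in floors], dtype=float)
        return floors, p

    def mean(self) -> float:
        floors, p = self.as_arrays()
        return float(floors @ p)


@dataclass
class JointAttributeTable:
    """Joint P(u, f) and conditional P(f | u) per building."""

    use_types: np.ndarray          # (U,)
    floors: np.ndarray             # (F,)
    joint: np.ndarray              # (U, F), sums to 1
    conditional: np.ndarray        # (U, F); rows with zero marginal are NaN
    use_marginal: np.ndarray       # (U,)

    def conditional_for(self, use_type: str) -> dict[int, float]:
        i = int(np.where(self.use_types == use_type)[0][0])
        if self.use_marginal[i] <= 0:
            raise ValueError(f"use type {use_type!r} has zero marginal probability")
        return {int(f): float(p) for f, p in zip(self.floors, self.conditional[i])}


@dataclass
class EnsembleModel:
    """A trained forest plus everything needed to reproduce predictions."""

    task: str                       # "usetype" | "floors"
    estimator: object               # fitted RandomForest{Classifier,Regressor}
    feature_names: list[str]
    medians: pd.Series              # training-set medians for NaN imputation
    best_params: dict
    seed: int
    n_candidates: int
    holdout_report: dict = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return len(self.estimator.estimators_)

    def prepare(self, X) -> np.ndarray:
        """Validate schema and impute NaN sentinels with training medians."""
        if isinstance(X, pd.Series):
            X = X.to_frame().T
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            if missing:
                raise ValueError(f"feature schema mismatch; missing columns {missing}")
            X = X[self.feature_names]
        else:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            if X.shape[1] != len(self.feature_names):
                raise ValueError(
                    f"feature schema mismatch; expected {len(self.feature_names)} "
                    f"columns, got {X.shape[1]}"
                )
            X = pd.DataFrame(X, columns=self.feature_names)
        return X.fillna(self.medians).to_numpy(dtype=float)


def dominant_label(shares: Mapping[str, float]) -> str:
    """Largest-share label when a building carries multiple labels."""
    if not shares:
        raise ValueError("no labels supplied")
    return max(shares, key=lambda k: (shares[k], k))


def _validate_training(X: pd.DataFrame, y: Sequence) -> tuple[pd.DataFrame, np.ndarray]:
    if len(X) == 0:
        raise ValueError("empty training set")
    y = np.asarray(y)
    if len(y) != len(X):
        raise ValueError("feature/label length mismatch")
    return X, y


def train_use_type_model(
    features: pd.DataFrame,
    labels: Sequence[str],
    grid: Optional[dict] = None,
    seed: int = 42,
    n_estimators: int = 100,
    cv: int = 3,
    holdout_fraction: float = 0.2,
    n_jobs: int = 1,
) -> EnsembleModel:
    """Grid-searched random-forest classifier over the 8 use types.

    Model selection is an exhaustive grid search (3-fold CV, macro-averaged
    F1); a random 20% holdout report with per-class precision/recall/F1 is
    stored on the returned model.
    """
    grid = dict(grid) if grid is not None else dict(DEFAULT_GRID)
    features, labels = _validate_training(features, labels)

    unknown = set(labels) - set(USE_TYPES)
    if unknown:
        raise ValueError(f"labels outside the 8 use-type categories: {sorted(unknown)}")
    present = [u for u in USE_TYPES if u in set(labels)]
    absent = [u for u in USE_TYPES if u not in present]
    if absent:
        warnings.warn(f"use types with zero training examples excluded: {absent}")
    if len(present) < 2:
        raise ValueError("need at least 2 use-type classes to train a classifier")

    medians = features.median(numeric_only=True)
    X = features.fillna(medians).to_numpy(dtype=float)
    y = np.asarray(labels)

    X_tr, X_ho, y_tr, y_ho = train_test_split(
        X, y, test_size=holdout_fraction, random_state=seed, stratify=y
    )
    search = GridSearchCV(
        RandomForestClassifier(n_estimators=n_estimators, random_state=seed),
        param_grid=grid,
        scoring="f1_macro",
        cv=cv,
        n_jobs=n_jobs,
    )
    search.fit(X_tr, y_tr)

    report = classification_report(
        y_ho, search.best_estimator_.predict(X_ho), output_dict=True, zero_division=0
    )
    report["macro_f1"] = f1_score(
        y_ho, search.best_estimator_.predict(X_ho), average="macro"
    )
    return EnsembleModel(
        task="usetype",
        estimator=search.best_estimator_,
        feature_names=list(features.columns),
        medians=medians,
        best_params=search.best_params_,
        seed=seed,
        n_candidates=len(search.cv_results_["params"]),
        holdout_report=report,
    )


def train_floor_model(
    features: pd.DataFrame,
    floor_labels: Sequence[float],
    grid: Optional[dict] = None,
    seed: int = 42,
    n_estimators: int = 100,
    cv: int = 3,
    holdout_fraction: float = 0.2,
    n_jobs: int = 1,
) -> EnsembleModel:
    """Grid-searched random-forest regressor on floor counts.

    Scored by cross-validated mean absolute error; the holdout report also
    carries the MAE/RMSE of the constant-1.5 and constant-2 default
    heuristics for comparison.
    """
    grid = dict(grid) if grid is not None else dict(DEFAULT_GRID)
    features, y = _validate_training(features, floor_labels)
    y = y.astype(float)
    if np.any(y < 1):
        raise ValueError("floor labels must be >= 1")

    medians = features.median(numeric_only=True)
    X = features.fillna(medians).to_numpy(dtype=float)

    X_tr, X_ho, y_tr, y_ho = train_test_split(
        X, y, test_size=holdout_fraction, random_state=seed
    )
    search = GridSearchCV(
        RandomForestRegressor(n_estimators=n_estimators, random_state=seed),
        param_grid=grid,
        scoring="neg_mean_absolute_error",
        cv=cv,
        n_jobs=n_jobs,
    )
    search.fit(X_tr, y_tr)

    pred = search.best_estimator_.predict(X_ho)
    report = {
        "mae": float(mean_absolute_error(y_ho, pred)),
        "rmse": float(np.sqrt(np.mean((y_ho - pred) ** 2))),
        "mae_heuristic_1.5": float(np.mean(np.abs(y_ho - 1.5))),
        "mae_heuristic_2": float(np.mean(np.abs(y_ho - 2.0))),
    }
    return EnsembleModel(
        task="floors",
        estimator=search.best_estimator_,
        feature_names=list(features.columns),
        medians=medians,
        best_params=search.best_params_,
        seed=seed,
        n_candidates=len(search.cv_results_["params"]),
        holdout_report=report,
    )


def _tree_votes(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Per-tree predicted class labels, shape (T, n)."""
    rf = model.estimator
    idx = np.stack([est.predict(X) for est in rf.estimators_]).astype(int)
    return rf.classes_[idx]


def votes_to_use_distribution(votes: Sequence[str]) -> UseTypeDistribution:
    """Tally per-tree class votes into vote-fraction probabilities.

    With T trees every probability is a multiple of 1/T; e.g. 10 trees
    voting 5/3/2 for Residential/Commercial/Retail give {0.5, 0.3, 0.2}.
    """
    votes = np.asarray(votes, dtype=object)
    if len(votes) == 0:
        raise ValueError("no votes supplied")
    T = len(votes)
    labels, counts = np.unique(votes, return_counts=True)
    return UseTypeDistribution({str(u): c / T for u, c in zip(labels, counts)})


def predict_use_type_distribution(model: EnsembleModel, x) -> UseTypeDistribution:
    """Vote-fraction distribution over use types for a single building."""
    if model.task != "usetype":
        raise ValueError("model was not trained for use-type classification")
    X = model.prepare(x)
    return votes_to_use_distribution(_tree_votes(model, X)[:, 0])


def round_floors(raw: np.ndarray) -> np.ndarray:
    """Round-half-to-even, clamped to a minimum of one floor."""
    return np.maximum(np.rint(np.asarray(raw, dtype=float)), 1.0).astype(int)


def tree_outputs_to_floor_distribution(raw: Sequence[float]) -> FloorDistribution:
    """Round per-tree continuous outputs (2.09 -> 2, 1.1 -> 1) and tally."""
    rounded = round_floors(np.asarray(raw, dtype=float))
    T = len(rounded)
    if T == 0:
        raise ValueError("no tree outputs supplied")
    floors, counts = np.unique(rounded, return_counts=True)
    return FloorDistribution({int(f): c / T for f, c in zip(floors, counts)})


def predict_floor_distribution(model: EnsembleModel, x) -> FloorDistribution:
    """Per-tree regression outputs rounded and tallied into a distribution."""
    if model.task != "floors":
        raise ValueError("model was not trained for floor-count regression")
    X = model.prepare(x)
    raw = np.array([est.predict(X)[0] for est in model.estimator.estimators_])
    return tree_outputs_to_floor_distribution(raw)


def build_joint_conditional(
    u_dist: UseTypeDistribution, f_dist: FloorDistribution
) -> JointAttributeTable:
    """Normalized outer-product joint and the conditional P(f | u).

    With independent marginals the conditional reduces to the floor marginal
    for every use type with positive mass; the construction still pins the
    feasible floor support to the drawn use type, and an externally supplied
    joint may replace it where dependence information exists.
    """
    u_labels, u_p = u_dist.as_arrays()
    floors, f_p = f_dist.as_arrays()
    if u_p.sum() <= 0 or f_p.sum() <= 0:
        raise ValueError("degenerate empty distributions")
    joint = np.outer(u_p, f_p)
    joint = joint / joint.sum()
    marg = joint.sum(axis=1)
    cond = np.full_like(joint, np.nan)
    nz = marg > 0
    cond[nz] = joint[nz] / marg[nz, None]
    return JointAttributeTable(
        use_types=u_labels, floors=floors, joint=joint,
        conditional=cond, use_marginal=marg,
    )
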