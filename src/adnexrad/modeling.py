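"""Risk-model training: stratified split, tuned classifiers, predictions.

Two model variants are supported on top of the selected radiomics features:

* radiomics-only — any of four algorithm families (penalized logistic
  regression, random forest, gradient-boosted trees via XGBoost, SVM);
* clinical-radiomics — the radiomics features plus age and serum CA 125.
  CA 125 is missing for a quarter of cases and is *never imputed*; the
  clinical variant is therefore restricted to the tree learners, which route
  missing values natively. Non-tree algorithms refuse matrices containing
  NaN.

Hyperparameters are tuned by randomized search over a modest documented grid
with stratified 5-fold cross-validation, selecting on mean CV AUC, then the
winner is refit on the full training split. All randomness is seeded.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RandomizedSearchCV, StratifiedKFold
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .selection import FrozenScaler

ALGORITHMS = ("penalized_logistic", "random_forest", "gradient_boosted_trees", "svm")
TREE_ALGORITHMS = ("random_forest", "gradient_boosted_trees")


@dataclass
class SplitSpec:
    """70:30 stratified train/validation split over the five outcome strata."""

    train_fraction: float = 0.70
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def stratified_split(cohort, spec: SplitSpec | None = None) -> tuple[list[str], list[str]]:
    """Partition case ids into (train, validation) per-stratum.

    The validation count per stratum is round-half-up of
    (1 - train_fraction) x stratum size; the partition is random within each
    stratum and deterministic given the seed.
    """
    spec = spec or SplitSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    by_stratum: dict[str, list[str]] = {}
    for c in cohort:
        by_stratum.setdefault(c.outcome, []).append(c.case_id)
    train_ids: list[str] = []
    val_ids: list[str] = []
    for stratum in sorted(by_stratum):
        ids = by_stratum[stratum]
        if len(ids) < 2:
            raise ValueError(f"stratum {stratum!r} has < 2 cases; split degenerate")
        idx = rng.permutation(len(ids))
        n_val = int(np.floor((1.0 - spec.train_fraction) * len(ids) + 0.5))
        n_val = min(max(n_val, 1), len(ids) - 1)
        val_ids.extend(ids[i] for i in idx[:n_val])
        train_ids.extend(ids[i] for i in idx[n_val:])
    return sorted(train_ids), sorted(val_ids)


# ---------------------------------------------------------------------------
# Hyperparameter grids (the source study names none; these are deliberately
# modest, documented spaces)

def _search_space(algorithm: str, seed: int) -> tuple[BaseEstimator, dict]:
    if algorithm == "penalized_logistic":
        est = LogisticRegression(max_iter=5000, solver="liblinear")
        space = {
            "C": sps.loguniform(1e-3, 1e2),
            "penalty": ["l1", "l2"],
        }
    elif algorithm == "random_forest":
        est = RandomForestClassifier(random_state=seed, n_jobs=1)
        space = {
            "n_estimators": sps.randint(100, 601),
            "max_depth": sps.randint(2, 13),
            "min_samples_leaf": sps.randint(1, 11),
            "max_features": ["sqrt", 0.5, 0.8],
        }
    elif algorithm == "gradient_boosted_trees":
        est = XGBClassifier(random_state=seed, n_jobs=1, tree_method="hist",
                            eval_metric="logloss")
        space = {
            "n_estimators": sps.randint(100, 601),
            "max_depth": sps.randint(2, 7),
            "learning_rate": sps.loguniform(0.01, 0.3),
            "subsample": sps.uniform(0.6, 0.4),
            "colsample_bytree": sps.uniform(0.6, 0.4),
            "reg_lambda": sps.loguniform(1e-2, 1e2),
        }
    elif algorithm == "svm":
        est = SVC(probability=True, random_state=seed)
        space = {
            "C": sps.loguniform(1e-2, 1e2),
            "kernel": ["rbf", "linear"],
            "gamma": ["scale", "auto"],
        }
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    return est, space


class RiskModel(BaseEstimator, ClassifierMixin):
    """Tuned binary malignancy-risk classifier with a frozen feature scaler.

    Parameters
    ----------
    algorithm : one of ``ALGORITHMS``.
    cv_folds : folds of the stratified CV used for tuning (default 5).
    n_search : randomized-search draws (default 25).
    random_state : seed for search, CV shuffling and the learner.

    Fitted attributes
    -----------------
    feature_names_ : training feature order.
    scaler_ : :class:`FrozenScaler` with training-split statistics.
    best_params_ : winning hyperparameters.
    cv_auc_ : mean 5-fold CV AUC of the winner.
    estimator_ : the refit underlying learner.
    """

    def __init__(self, algorithm: str = "gradient_boosted_trees", cv_folds: int = 5,
                 n_search: int = 25, random_state: int = 0):
        self.algorithm = algorithm
        self.cv_folds = cv_folds
        self.n_search = n_search
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = np.asarray(y).astype(int)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError("binary outcome required")
        if counts.min() < self.cv_folds:
            raise ValueError(f"need >= {self.cv_folds} cases per class for "
                             f"{self.cv_folds}-fold CV")
        if self.algorithm not in TREE_ALGORITHMS and X.isna().to_numpy().any():
            raise ValueError(
                f"algorithm {self.algorithm!r} cannot handle missing values "
                "(e.g. serum CA 125); use a tree-based algorithm")
        self.feature_names_ = list(X.columns)
        self.scaler_ = FrozenScaler.fit(X)
        Xs = self.scaler_.apply(X).to_numpy(float)
        est, space = _search_space(self.algorithm, self.random_state)
        cv = StratifiedKFold(n_splits=self.cv_folds, shuffle=True,
                             random_state=self.random_state)
        search = RandomizedSearchCV(
            est, space, n_iter=self.n_search, scoring="roc_auc", cv=cv,
            random_state=self.random_state, n_jobs=1, refit=True,
            error_score="raise")
        search.fit(Xs, y)
        self.best_params_ = search.best_params_
        self.cv_auc_ = float(search.best_score_)
        self.estimator_ = search.best_estimator_
        self.classes_ = classes
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)
        unknown = [c for c in X.columns if c not in self.feature_names_]
        if unknown:
            raise KeyError(f"unknown feature names: {unknown}")
        Xs = self.scaler_.apply(X[self.feature_names_]).to_numpy(float)
        if self.algorithm not in TREE_ALGORITHMS and np.isnan(Xs).any():
            raise ValueError(f"algorithm {self.algorithm!r} cannot predict with "
                             "missing values")
        return self.estimator_.predict_proba(Xs)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of malignancy per case, in [0, 1]."""
        return self.predict_proba(X)[:, 1]


def tune_and_train(algorithm: str, train: pd.DataFrame, labels, cv_folds: int = 5,
                   n_search: int = 25, seed: int = 0) -> RiskModel:
    """Randomized-search tuning + refit; returns the fitted :class:`RiskModel`."""
    model = RiskModel(algorithm=algorithm, cv_folds=cv_folds, n_search=n_search,
                      random_state=seed)
    return model.fit(train, labels)


def predict_risk(model: RiskModel, X: pd.DataFrame, model_id: str = "") -> pd.DataFrame:
    """Per-case malignancy risks as a DataFrame (case_id, model_id, risk)."""
    risks = model.predict_risk(X)
    return pd.DataFrame({
        "case_id": list(X.index),
        "model_id": model_id or model.algorithm,
        "risk": risks,
    })


def events_per_variable(n_events: int, n_predictors: int) -> tuple[float, bool]:
    """Events-per-variable ratio to 2 decimals and a <10 adequacy flag."""
    if n_predictors < 1:
        raise ValueError("n_predictors must be >= 1")
    ratio = Decimal(n_events) / Decimal(n_predictors)
    rounded = float(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    return rounded, rounded < 10.0


def proportion_percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Cohort bookkeeping: 100 * numerator / denominator, half-up rounded."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    q = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def gain_importance(model: RiskModel) -> dict[str, float]:
    """Per-feature mean split gain of a tree model, normalized to sum 1."""
    if model.algorithm not in TREE_ALGORITHMS:
        raise ValueError("gain importance is defined for tree-based models only")
    names = model.feature_names_
    if model.algorithm == "gradient_boosted_trees":
        booster = model.estimator_.get_booster()
        raw = booster.get_score(importance_type="gain")
        gains = np.array([raw.get(f"f{i}", 0.0) for i in range(len(names))])
    else:
        # impurity-decrease importances: the random-forest analogue of gain
        gains = np.asarray(model.estimator_.feature_importances_, dtype=float)
    total = gains.sum()
    if total <= 0:
        raise ValueError("model has no informative splits")
    norm = gains / total
    order = np.argsort(-norm)
    return {names[i]: float(norm[i]) for i in order}
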