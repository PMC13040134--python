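"""Statistical feature selection.

The primary cascade reduces the 74 radiomics features to a non-redundant
informative subset:

1. per-feature two-tailed Mann-Whitney U test of benign vs malignant on the
   training split (exact enumeration when both groups have <= 8 cases,
   normal approximation with tie and continuity correction otherwise);
2. Benjamini-Hochberg step-up adjustment at alpha = 0.05;
3. greedy redundancy pruning: significant features are visited in ascending
   MWU-p order (ties broken by registry order) and accepted iff their
   absolute Pearson correlation with every already-accepted feature is
   <= 0.6 on the training split, so of any correlated group the feature with
   the lowest p-value survives.

MRMR and RFE are provided as alternate selectors for overfitting checks.
Selection and the frozen Z-scaler are always fit on the training split only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import RFE


@dataclass
class SelectionResult:
    """Outcome of a selection run on the training split."""

    p_values: dict[str, float]
    adjusted_p: dict[str, float]
    significant: list[str]
    kept: list[str]
    method: str = "mwu_bh_pearson"
    alpha: float = 0.05
    r_threshold: float = 0.6

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        return cls(**json.loads(Path(path).read_text()))


def mwu_screen(train: pd.DataFrame, labels) -> dict[str, float]:
    """Two-tailed Mann-Whitney U p-value per feature column."""
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    g0 = train.loc[y == 0]
    g1 = train.loc[y == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("need >= 2 cases per class")
    method = "exact" if max(len(g0), len(g1)) <= 8 else "asymptotic"
    out: dict[str, float] = {}
    for name in train.columns:
        a, b = g0[name].to_numpy(float), g1[name].to_numpy(float)
        m = method
        if m == "exact" and (np.unique(np.concatenate([a, b])).size
                             < a.size + b.size):
            m = "asymptotic"  # scipy's exact method does not handle ties
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=m,
                                 use_continuity=True)
        out[name] = float(res.pvalue)
    return out


def bh_adjust(p_values: dict[str, float] | np.ndarray, alpha: float = 0.05):
    """Benjamini-Hochberg step-up adjusted p-values and the significant set.

    Returns ``(adjusted, significant)`` where ``adjusted`` mirrors the input
    container type and ``significant`` lists names (or indices) with adjusted
    p <= alpha.
    """
    names = None
    if isinstance(p_values, dict):
        names = list(p_values.keys())
        p = np.array([p_values[k] for k in names], dtype=float)
    else:
        p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m, dtype=float)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        adj[idx] = running
    if names is not None:
        adjusted = {k: float(adj[i]) for i, k in enumerate(names)}
        significant = [k for k in names if adjusted[k] <= alpha]
        return adjusted, significant
    return adj, list(np.flatnonzero(adj <= alpha))


def prune_correlated(train: pd.DataFrame, significant: list[str],
                     p_values: dict[str, float], threshold: float = 0.6) -> list[str]:
    """Greedy Pearson-redundancy pruning of the significant features.

    Features are visited by ascending p (ties: column order of ``train``) and
    accepted iff |r| <= ``threshold`` against every already-accepted feature.
    Zero-variance features are excluded with a warning.
    """
    if not significant:
        raise ValueError("significant feature list is empty")
    col_rank = {name: i for i, name in enumerate(train.columns)}
    ordered = sorted(significant, key=lambda f: (p_values[f], col_rank[f]))
    kept: list[str] = []
    for f in ordered:
        x = train[f].to_numpy(float)
        if np.std(x) == 0:
            warnings.warn(f"feature {f!r} has zero variance on the training set; excluded")
            continue
        ok = True
        for g in kept:
            r = np.corrcoef(x, train[g].to_numpy(float))[0, 1]
            if abs(r) > threshold:
                ok = False
                break
        if ok:
            kept.append(f)
    return kept


@dataclass
class FrozenScaler:
    """Per-feature Z-scaler with statistics frozen on the training split.

    Uses the sample SD (n-1 denominator). NaN cells (missing CA125) are
    ignored when estimating statistics and propagate unchanged through
    ``apply`` so that tree learners can route them natively.
    """

    means: dict[str, float]
    sds: dict[str, float]

    @classmethod
    def fit(cls, train: pd.DataFrame) -> "FrozenScaler":
        if train.empty:
            raise ValueError("training matrix is empty")
        means, sds = {}, {}
        for name in train.columns:
            x = train[name].to_numpy(float)
            x = x[~np.isnan(x)]
            sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
            if sd == 0.0:
                raise ValueError(f"feature {name!r} has zero SD on the training set")
            means[name] = float(np.mean(x))
            sds[name] = sd
        return cls(means=means, sds=sds)

    def apply(self, matrix: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.means if c not in matrix.columns]
        if missing:
            raise KeyError(f"matrix lacks scaled features: {missing}")
        out = matrix[list(self.means)].astype(float).copy()
        for name in self.means:
            out[name] = (out[name] - self.means[name]) / self.sds[name]
        return out


def scale_features(train: pd.DataFrame, apply_to: pd.DataFrame | None = None):
    """Fit a Z-scaler on ``train`` and apply it to ``apply_to`` (or train).

    Returns ``(scaled, scaler)`` with frozen training statistics.
    """
    scaler = FrozenScaler.fit(train)
    target = train if apply_to is None else apply_to
    return scaler.apply(target), scaler


# ---------------------------------------------------------------------------
# Alternate selectors

def mrmr_select(train: pd.DataFrame, labels, k: int) -> list[str]:
    """Greedy minimum-redundancy maximum-relevance selection.

    Relevance = |point-biserial Pearson r| with the binary label; redundancy
    = mean |Pearson r| with the already-selected set. At each step the
    feature maximizing relevance - redundancy is added (ties: column order).
    """
    y = np.asarray(labels, dtype=float)
    cols = list(train.columns)
    if not 1 <= k <= len(cols):
        raise ValueError(f"k must be in [1, {len(cols)}], got {k}")
    X = train.to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.abs(np.array([np.corrcoef(X[:, j], y)[0, 1] for j in range(X.shape[1])]))
    rel = np.nan_to_num(rel)
    selected: list[int] = []
    remaining = list(range(len(cols)))
    corr_cache: dict[tuple[int, int], float] = {}

    def absr(a: int, b: int) -> float:
        key = (min(a, b), max(a, b))
        if key not in corr_cache:
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.corrcoef(X[:, a], X[:, b])[0, 1]
            corr_cache[key] = abs(float(np.nan_to_num(r)))
        return corr_cache[key]

    while len(selected) < k:
        best_j, best_score = None, -np.inf
        for j in remaining:
            red = (np.mean([absr(j, s) for s in selected]) if selected else 0.0)
            score = rel[j] - red
            if score > best_score + 1e-15:
                best_j, best_score = j, score
        selected.append(best_j)
        remaining.remove(best_j)
    return [cols[j] for j in selected]


def rfe_select(estimator, train: pd.DataFrame, labels, k: int) -> list[str]:
    """Recursive feature elimination down to ``k`` features."""
    if not 1 <= k <= train.shape[1]:
        raise ValueError(f"k must be in [1, {train.shape[1]}], got {k}")
    rfe = RFE(estimator, n_features_to_select=k, step=1)
    rfe.fit(train.to_numpy(float), np.asarray(labels).astype(int))
    return [c for c, keep in zip(train.columns, rfe.support_) if keep]


# ---------------------------------------------------------------------------
# sklearn-style selector

class MWUBHSelector(BaseEstimator, TransformerMixin):
    """Selector implementing the MWU -> BH -> Pearson-pruning cascade.

    Parameters
    ----------
    alpha : BH significance level (default 0.05).
    r_threshold : absolute Pearson correlation above which two features are
        considered redundant (default 0.6).

    Fitted attributes
    -----------------
    p_values_, adjusted_p_ : dict feature -> p.
    significant_ : features surviving BH at ``alpha``.
    kept_ : final non-redundant feature list.
    result_ : the full :class:`SelectionResult`.
    """

    def __init__(self, alpha: float = 0.05, r_threshold: float = 0.6):
        self.alpha = alpha
        self.r_threshold = r_threshold

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        self.p_values_ = mwu_screen(X, y)
        self.adjusted_p_, self.significant_ = bh_adjust(self.p_values_, self.alpha)
        if self.significant_:
            self.kept_ = prune_correlated(X, self.significant_, self.p_values_,
                                          self.r_threshold)
        else:
            # nothing survives multiple-testing correction (e.g. a null
            # cohort): keep the single best-ranked feature so downstream
            # modeling stays runnable, and say so
            fallback = min(self.p_values_, key=self.p_values_.get)
            warnings.warn("no feature significant after BH correction; "
                          f"keeping best-ranked feature {fallback!r} only")
            self.kept_ = [fallback]
        self.result_ = SelectionResult(
            p_values=self.p_values_, adjusted_p=self.adjusted_p_,
            significant=self.significant_, kept=self.kept_,
            method="mwu_bh_pearson", alpha=self.alpha,
            r_threshold=self.r_threshold)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.kept_]
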