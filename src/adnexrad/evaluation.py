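"""Validation battery: discrimination, classification, calibration, utility.

Implements the full evaluation a risk model for malignancy triage needs:

* AUC via the rank (Mann-Whitney concordance) identity with a stratified
  percentile-bootstrap 95% CI;
* DeLong's test for the difference between two paired AUCs;
* sensitivity / specificity / PPV / NPV / accuracy / likelihood ratios at a
  probability cutoff (positive iff risk >= cutoff), normal-approximation CIs
  for proportions and log-method CIs for likelihood ratios;
* Youden-optimal cutoff (ties resolved toward the lowest cutoff, i.e. the
  more sensitive operating point);
* calibration intercept and slope from a logistic recalibration model plus a
  nonparametric (local-linear) calibration curve;
* decision-curve analysis (net benefit over a 1-50% threshold grid);
* the per-feature SHAP "Overfit_Score" (mean |SHAP| on train minus mean
  |SHAP| on validation) using exact TreeSHAP attributions;
* a PCA diagnostic for manufacturer effects on the selected features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import PCA

from .modeling import RiskModel


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return y


def _rank_auc(risks: np.ndarray, y: np.ndarray) -> float:
    """AUC = (R1 - n1(n1+1)/2) / (n1 n0), ties counted 1/2 via midranks."""
    ranks = stats.rankdata(risks)
    n1 = int(y.sum())
    n0 = y.size - n1
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def auc(risks, labels, n_boot: int = 2000, seed: int = 0,
        ci_level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """AUC with a stratified percentile-bootstrap confidence interval."""
    y = _check_binary(labels)
    r = np.asarray(risks, dtype=float)
    point = _rank_auc(r, y)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.choice(pos, size=pos.size, replace=True)
        ineg = rng.choice(neg, size=neg.size, replace=True)
        idx = np.concatenate([ip, ineg])
        boots[b] = _rank_auc(r[idx], y[idx])
    alpha = 1.0 - ci_level
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return point, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# DeLong

def _placements(risks: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Midrank placement values V10 (per positive) and V01 (per negative)."""
    pos = risks[y == 1]
    neg = risks[y == 0]
    m, n = pos.size, neg.size
    allr = np.concatenate([pos, neg])
    mid = stats.rankdata(allr)
    mid_pos = stats.rankdata(pos)
    mid_neg = stats.rankdata(neg)
    v10 = (mid[:m] - mid_pos) / n
    v01 = 1.0 - (mid[m:] - mid_neg) / m
    theta = float(v10.mean())
    return v10, v01, theta


def delong_compare(risks_a, risks_b, labels) -> tuple[float, float]:
    """Two-sided DeLong p-value for the paired AUC difference (and the z).

    Both risk vectors must be predictions for the *same* cases in the same
    order. Identical vectors give p = 1 by convention (zero difference, zero
    variance).
    """
    y = _check_binary(labels)
    a = np.asarray(risks_a, dtype=float)
    b = np.asarray(risks_b, dtype=float)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("risk vectors must be paired with the labels")
    v10a, v01a, th_a = _placements(a, y)
    v10b, v01b, th_b = _placements(b, y)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = th_a - th_b
    if var <= 0:
        return (1.0, 0.0) if abs(diff) < 1e-12 else (0.0, np.inf)
    z = diff / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(p), float(z)


def delong_variance(risks, labels) -> float:
    """DeLong variance of a single AUC (midrank placements)."""
    y = _check_binary(labels)
    v10, v01, _ = _placements(np.asarray(risks, dtype=float), y)
    return float(np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size)


# ---------------------------------------------------------------------------
# Classification at a cutoff

@dataclass
class ClassificationMetrics:
    """Confusion-matrix metrics at one probability cutoff, with 95% CIs."""

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    lr_pos: float
    lr_neg: float
    ci: dict[str, tuple[float, float] | None] = field(default_factory=dict)

    def as_row(self) -> dict[str, float]:
        return {"cutoff": self.cutoff, "accuracy": self.accuracy,
                "sensitivity": self.sensitivity, "specificity": self.specificity,
                "ppv": self.ppv, "npv": self.npv,
                "lr_pos": self.lr_pos, "lr_neg": self.lr_neg}


def _prop_ci(p: float, n: int) -> tuple[float, float] | None:
    if n == 0:
        return None
    half = 1.96 * np.sqrt(p * (1 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


def metrics_at_cutoff(risks, labels, cutoff: float) -> ClassificationMetrics:
    """Classification metrics at ``cutoff`` (positive iff risk >= cutoff)."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must be in (0, 1)")
    y = _check_binary(labels)
    pred = np.asarray(risks, dtype=float) >= cutoff
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    n_pos, n_neg = tp + fn, tn + fp
    sens = tp / n_pos if n_pos else np.nan
    spec = tn / n_neg if n_neg else np.nan
    ppv = tp / (tp + fp) if tp + fp else np.nan
    npv = tn / (tn + fn) if tn + fn else np.nan
    acc = (tp + tn) / y.size
    lr_pos = sens / (1 - spec) if spec < 1 else np.inf
    lr_neg = (1 - sens) / spec if spec > 0 else np.inf
    ci: dict[str, tuple[float, float] | None] = {
        "sensitivity": _prop_ci(sens, n_pos),
        "specificity": _prop_ci(spec, n_neg),
        "ppv": _prop_ci(ppv, tp + fp) if tp + fp else None,
        "npv": _prop_ci(npv, tn + fn) if tn + fn else None,
        "accuracy": _prop_ci(acc, y.size),
    }
    # log-method CIs for likelihood ratios
    if tp and fp and np.isfinite(lr_pos) and lr_pos > 0:
        se = np.sqrt(1 / tp - 1 / n_pos + 1 / fp - 1 / n_neg)
        ci["lr_pos"] = (float(lr_pos * np.exp(-1.96 * se)),
                        float(lr_pos * np.exp(1.96 * se)))
    else:
        ci["lr_pos"] = None
    if fn and tn and np.isfinite(lr_neg) and lr_neg > 0:
        se = np.sqrt(1 / fn - 1 / n_pos + 1 / tn - 1 / n_neg)
        ci["lr_neg"] = (float(lr_neg * np.exp(-1.96 * se)),
                        float(lr_neg * np.exp(1.96 * se)))
    else:
        ci["lr_neg"] = None
    return ClassificationMetrics(cutoff=cutoff, tp=tp, fp=fp, tn=tn, fn=fn,
                                 sensitivity=float(sens), specificity=float(spec),
                                 ppv=float(ppv), npv=float(npv), accuracy=float(acc),
                                 lr_pos=float(lr_pos), lr_neg=float(lr_neg), ci=ci)


def youden_cutoff(risks, labels) -> tuple[float, float]:
    """Cutoff maximizing Youden's J = sens + spec - 1 over observed risks.

    Ties are broken toward the lowest cutoff (the more sensitive operating
    point). Returns ``(cutoff, J)``.
    """
    y = _check_binary(labels)
    r = np.asarray(risks, dtype=float)
    best_c, best_j = None, -np.inf
    for c in np.unique(r):
        pred = r >= c
        sens = np.sum(pred & (y == 1)) / np.sum(y == 1)
        spec = np.sum(~pred & (y == 0)) / np.sum(y == 0)
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_c, best_j = float(c), float(j)
    return best_c, best_j


# ---------------------------------------------------------------------------
# Calibration

@dataclass
class CalibrationResult:
    intercept: float
    intercept_ci: tuple[float, float]
    slope: float
    slope_ci: tuple[float, float]
    curve: pd.DataFrame  # columns: predicted, observed


def _local_linear(x: np.ndarray, y: np.ndarray, grid: np.ndarray,
                  bandwidth: float) -> np.ndarray:
    """Local linear regression with a tricube kernel."""
    out = np.full(grid.size, np.nan)
    for g, x0 in enumerate(grid):
        u = np.abs(x - x0) / bandwidth
        w = np.where(u < 1, (1 - u ** 3) ** 3, 0.0)
        if w.sum() <= 0:
            continue
        X = np.column_stack([np.ones_like(x), x - x0])
        WX = X * w[:, None]
        beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ y, rcond=None)
        out[g] = beta[0]
    return out


def calibration(risks, labels, n_grid: int = 50,
                bandwidth_frac: float = 0.3) -> CalibrationResult:
    """Logistic recalibration intercept/slope + nonparametric curve.

    slope: coefficient of logit(risk) in a logistic fit of the labels;
    intercept: intercept of a logistic fit with logit(risk) as fixed offset.
    Intercept > 0 flags systematic risk underestimation, slope < 1 overly
    extreme risks. The curve is a local-linear smoother of outcome vs
    predicted risk on an even grid (bandwidth = ``bandwidth_frac`` of the
    observed risk range).
    """
    y = _check_binary(labels)
    r = np.clip(np.asarray(risks, dtype=float), 1e-6, 1 - 1e-6)
    if np.unique(r).size < 2:
        raise ValueError("constant risks: calibration slope undefined")
    lp = np.log(r / (1 - r))
    slope_fit = sm.GLM(y, sm.add_constant(lp), family=sm.families.Binomial()).fit()
    slope = float(slope_fit.params[1])
    s_ci = slope_fit.conf_int()[1]
    int_fit = sm.GLM(y, np.ones((y.size, 1)), family=sm.families.Binomial(),
                     offset=lp).fit()
    intercept = float(int_fit.params[0])
    i_ci = int_fit.conf_int()[0]
    grid = np.linspace(r.min(), r.max(), n_grid)
    bw = bandwidth_frac * max(r.max() - r.min(), 1e-6)
    observed = _local_linear(r, y.astype(float), grid, bw)
    curve = pd.DataFrame({"predicted": grid, "observed": observed})
    return CalibrationResult(intercept=intercept,
                             intercept_ci=(float(i_ci[0]), float(i_ci[1])),
                             slope=slope, slope_ci=(float(s_ci[0]), float(s_ci[1])),
                             curve=curve)


# ---------------------------------------------------------------------------
# Decision curves

def decision_curve(risks_by_model: dict[str, np.ndarray], labels,
                   grid: np.ndarray | None = None) -> pd.DataFrame:
    """Net benefit per model over a threshold grid, plus treat-all/none.

    NB(t) = TP(t)/n - FP(t)/n * t/(1-t); treat-all has TP = all positives and
    FP = all negatives; treat-none is identically zero.
    """
    y = _check_binary(labels)
    n = y.size
    prev = y.mean()
    if grid is None:
        grid = np.arange(0.01, 0.501, 0.01)
    grid = np.asarray(grid, dtype=float)
    if (grid <= 0).any() or (grid >= 1).any():
        raise ValueError("thresholds must lie in (0, 1)")
    out = {"threshold": grid,
           "treat_all": prev - (1 - prev) * grid / (1 - grid),
           "treat_none": np.zeros_like(grid)}
    for name, r in risks_by_model.items():
        r = np.asarray(r, dtype=float)
        nb = np.empty_like(grid)
        for i, t in enumerate(grid):
            pred = r >= t
            tp = np.sum(pred & (y == 1)) / n
            fp = np.sum(pred & (y == 0)) / n
            nb[i] = tp - fp * t / (1 - t)
        out[name] = nb
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# SHAP overfitting diagnostic

def shap_values(model: RiskModel, X: pd.DataFrame) -> np.ndarray:
    """Exact TreeSHAP attributions (log-odds scale) per case and feature."""
    import xgboost as xgb

    if model.algorithm != "gradient_boosted_trees":
        raise ValueError("exact TreeSHAP attributions are available for the "
                         "gradient-boosted-tree models only")
    Xs = model.scaler_.apply(pd.DataFrame(X)[model.feature_names_]).to_numpy(float)
    booster = model.estimator_.get_booster()
    contrib = booster.predict(xgb.DMatrix(Xs, feature_names=None),
                              pred_contribs=True)
    return contrib  # (n, p + 1); last column is the expected value


def shap_overfit_table(model: RiskModel, X_train: pd.DataFrame,
                       X_val: pd.DataFrame) -> pd.DataFrame:
    """Per-feature Overfit_Score = mean |SHAP| train - mean |SHAP| validation.

    A large positive score marks a feature the model leans on in training but
    not on unseen cases — the signature of memorization. Sorted descending.
    """
    c_tr = shap_values(model, X_train)[:, :-1]
    c_va = shap_values(model, X_val)[:, :-1]
    mean_tr = np.abs(c_tr).mean(axis=0)
    mean_va = np.abs(c_va).mean(axis=0)
    tab = pd.DataFrame({
        "feature": model.feature_names_,
        "mean_abs_shap_train": mean_tr,
        "mean_abs_shap_validation": mean_va,
        "overfit_score": mean_tr - mean_va,
    }).sort_values("overfit_score", ascending=False, kind="stable")
    return tab.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Manufacturer PCA diagnostic

def manufacturer_pca(train: pd.DataFrame, tags) -> tuple[pd.DataFrame, dict]:
    """PCA of Z-scaled selected features, summarized by manufacturer tag.

    Returns the first-two-component scores per case and a dispersion summary:
    mean pairwise distance between tag centroids divided by the mean
    within-tag RMS spread (small ratio = overlapping clusters = no
    manufacturer effect).
    """
    tags = np.asarray(tags)
    X = pd.DataFrame(train).to_numpy(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance feature in PCA input")
    Z = (X - mu) / sd
    pca = PCA(n_components=min(2, Z.shape[1]), svd_solver="full")
    scores = pca.fit_transform(Z)
    df = pd.DataFrame(scores, columns=[f"PC{i+1}" for i in range(scores.shape[1])],
                      index=pd.DataFrame(train).index)
    df["manufacturer"] = tags
    uniq = np.unique(tags)
    if uniq.size < 2:
        warnings.warn("single manufacturer tag: clusters trivially overlap")
        summary = {"overlap_ratio": 0.0,
                   "explained_variance_ratio": pca.explained_variance_ratio_.tolist()}
        return df, summary
    cents = {t: scores[tags == t].mean(axis=0) for t in uniq}
    spreads = [np.sqrt(np.mean(np.sum((scores[tags == t] - cents[t]) ** 2, axis=1)))
               for t in uniq]
    dists = [np.linalg.norm(cents[a] - cents[b])
             for i, a in enumerate(uniq) for b in uniq[i + 1:]]
    summary = {
        "overlap_ratio": float(np.mean(dists) / max(np.mean(spreads), 1e-12)),
        "explained_variance_ratio": pca.explained_variance_ratio_.tolist(),
    }
    return df, summary
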