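"""IBSI-style 2-D radiomics features: intensity statistics and texture families.

The feature set totals 74 named features over four families:

* 17 intensity-based statistical features computed on the continuous per-ROI
  Z-scores (population moments; kurtosis is *excess* kurtosis),
* 25 gray-level co-occurrence matrix (GLCM) features,
* 16 gray-level run-length matrix (GLRLM) features,
* 16 gray-level size-zone matrix (GLSZM) features.

Texture matrices are built from a fixed-bin-number discretization of the
Z-scored ROI (default 32 bins). GLCM uses distance-1 pairs in the four 2-D
directions (0, 45, 90, 135 degrees), symmetrized and *merged* (summed) over
directions before feature computation; GLRLM counts maximal runs per
direction, merged over the four directions; GLSZM uses 8-connected
constant-level zones and is direction-free. Pixels outside the ROI mask never
contribute to any pair, run or zone. All entropies use log base 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .preprocess import NormalizedROI, wiener_despeckle, zscore_roi

# ---------------------------------------------------------------------------
# Registry

INTENSITY_FEATURES = [
    "F.stat.mean", "F.stat.var", "F.stat.skew", "F.stat.kurt", "F.stat.median",
    "F.stat.min", "F.stat.P10", "F.stat.P90", "F.stat.max", "F.stat.iqr",
    "F.stat.range", "F.stat.mad", "F.stat.rmad", "F.stat.medad",
    "F.stat.energy", "F.stat.rms", "F.stat.entropy",
]

GLCM_FEATURES = [
    "F_cm.joint.max", "F_cm.joint.avg", "F_cm.joint.var", "F_cm.joint.entr",
    "F_cm.diff.avg", "F_cm.diff.var", "F_cm.diff.entr",
    "F_cm.sum.avg", "F_cm.sum.var", "F_cm.sum.entr",
    "F_cm.energy", "F_cm.contrast", "F_cm.dissimilarity",
    "F_cm.inv.diff", "F_cm.inv.diff.norm", "F_cm.inv.diff.mom",
    "F_cm.inv.diff.mom.norm", "F_cm.inv.var", "F_cm.corr", "F_cm.auto.corr",
    "F_cm.clust.tend", "F_cm.clust.shade", "F_cm.clust.prom",
    "F_cm.info.corr.1", "F_cm.info.corr.2",
]

GLRLM_FEATURES = [
    "F_rlm.sre", "F_rlm.lre", "F_rlm.lgre", "F_rlm.hgre",
    "F_rlm.srlge", "F_rlm.srhge", "F_rlm.lrlge", "F_rlm.lrhge",
    "F_rlm.glnu", "F_rlm.glnu.norm", "F_rlm.rlnu", "F_rlm.rlnu.norm",
    "F_rlm.r.perc", "F_rlm.gl.var", "F_rlm.rl.var", "F_rlm.rl.entr",
]

GLSZM_FEATURES = [
    "F_szm.sze", "F_szm.lze", "F_szm.lgze", "F_szm.hgze",
    "F_szm.szlge", "F_szm.szhge", "F_szm.lzlge", "F_szm.lzhge",
    "F_szm.glu", "F_szm.glu.norm", "F_szm.zsnu", "F_szm.zsnu.norm",
    "F_szm.z.perc", "F_szm.gl.var", "F_szm.zs.var", "F_szm.zs.entr",
]

#: Ordered names of all 74 features.
FEATURE_REGISTRY: tuple[str, ...] = tuple(
    INTENSITY_FEATURES + GLCM_FEATURES + GLRLM_FEATURES + GLSZM_FEATURES
)

assert len(FEATURE_REGISTRY) == 74


@dataclass
class FeatureVector:
    """Named radiomics features for one case."""

    values: dict[str, float]
    case_id: str = ""
    n_bins: int = 32

    def as_array(self) -> np.ndarray:
        return np.array([self.values[name] for name in FEATURE_REGISTRY])


@dataclass
class TextureMatrices:
    """Gray-level co-occurrence, run-length and size-zone count matrices.

    ``glcm[i-1, j-1]`` counts symmetric distance-1 pairs of levels (i, j)
    merged over the four directions; ``glrlm[i-1, l-1]`` counts maximal runs
    of level i and length l merged over the four directions;
    ``glszm[i-1, s-1]`` counts 8-connected zones of level i and size s.
    """

    glcm: np.ndarray
    glrlm: np.ndarray
    glszm: np.ndarray
    n_levels: int
    n_pixels: int
    n_directions: int = 4


# ---------------------------------------------------------------------------
# Discretization

def discretize(roi: NormalizedROI, n_bins: int = 32) -> np.ndarray:
    """Fixed-bin-number discretization of ROI Z-scores.

    Equal-width bins span [min, max] of the in-mask values; labels run
    1..n_bins with label = max(1, ceil(n_bins * (x - min) / range)), so the
    minimum maps to 1 and the maximum to n_bins. Returns a 2-D int array with
    0 outside the mask.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    vals = roi.pixels
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        # cannot happen for a ROI that passed Z-scoring, but guard anyway
        labels_in = np.ones(vals.shape, dtype=np.int64)
    else:
        labels_in = np.ceil(n_bins * (vals - lo) / (hi - lo)).astype(np.int64)
        labels_in[labels_in < 1] = 1
        labels_in[labels_in > n_bins] = n_bins
    labels = np.zeros(roi.mask.shape, dtype=np.int64)
    labels[roi.mask] = labels_in
    return labels


# ---------------------------------------------------------------------------
# Intensity statistics

def _fbn_entropy(vals: np.ndarray, n_bins: int) -> float:
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        return 0.0
    lab = np.ceil(n_bins * (vals - lo) / (hi - lo)).astype(np.int64)
    lab[lab < 1] = 1
    lab[lab > n_bins] = n_bins
    p = np.bincount(lab, minlength=n_bins + 1)[1:].astype(np.float64)
    p = p / p.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def intensity_statistics(roi, n_bins: int = 32) -> dict[str, float]:
    """Intensity-based statistical features (population moments).

    ``roi`` may be a :class:`NormalizedROI` or any 1-D sequence of values.
    Kurtosis is excess kurtosis mu4/mu2^2 - 3; the histogram entropy uses the
    same fixed-bin-number discretization as the texture families.
    """
    if isinstance(roi, NormalizedROI):
        x = roi.pixels.astype(np.float64)
    else:
        x = np.asarray(roi, dtype=np.float64).ravel()
    n = x.size
    if n == 0:
        raise ValueError("empty ROI")
    mean = float(x.mean())
    d = x - mean
    mu2 = float((d * d).mean())
    mu3 = float((d ** 3).mean())
    mu4 = float((d ** 4).mean())
    skew = mu3 / mu2 ** 1.5 if mu2 > 0 else 0.0
    kurt = mu4 / mu2 ** 2 - 3.0 if mu2 > 0 else 0.0
    p10, p25, med, p75, p90 = (float(v) for v in np.percentile(x, [10, 25, 50, 75, 90]))
    core = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(core - core.mean()).mean()) if core.size else 0.0
    return {
        "F.stat.mean": mean,
        "F.stat.var": mu2,
        "F.stat.skew": skew,
        "F.stat.kurt": kurt,
        "F.stat.median": med,
        "F.stat.min": float(x.min()),
        "F.stat.P10": p10,
        "F.stat.P90": p90,
        "F.stat.max": float(x.max()),
        "F.stat.iqr": p75 - p25,
        "F.stat.range": float(x.max() - x.min()),
        "F.stat.mad": float(np.abs(d).mean()),
        "F.stat.rmad": rmad,
        "F.stat.medad": float(np.abs(x - med).mean()),
        "F.stat.energy": float((x * x).sum()),
        "F.stat.rms": float(np.sqrt((x * x).mean())),
        "F.stat.entropy": _fbn_entropy(x, n_bins),
    }


# ---------------------------------------------------------------------------
# Texture matrices

_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))  # 0, 45, 90, 135 degrees


def _direction_lines(labels: np.ndarray, offset: tuple[int, int]) -> list[np.ndarray]:
    """Lines of the label image along a direction (labels are 0 outside mask)."""
    dr, dc = offset
    if (dr, dc) == (0, 1):
        return [labels[i, :] for i in range(labels.shape[0])]
    if (dr, dc) == (-1, 0):
        return [labels[:, j] for j in range(labels.shape[1])]
    if (dr, dc) == (-1, 1):  # 45 deg: anti-diagonals
        flipped = labels[::-1, :]
        return [np.diagonal(flipped, k) for k in range(-(labels.shape[0] - 1), labels.shape[1])]
    if (dr, dc) == (-1, -1):  # 135 deg: main diagonals
        return [np.diagonal(labels, k) for k in range(-(labels.shape[0] - 1), labels.shape[1])]
    raise ValueError(f"unsupported offset {offset}")


def _run_lengths(lines: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Maximal-run values and lengths over a set of lines (0 = outside mask)."""
    if not lines:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    sep = np.array([0], dtype=np.int64)
    parts: list[np.ndarray] = []
    for ln in lines:
        parts.append(np.asarray(ln, dtype=np.int64))
        parts.append(sep)
    seq = np.concatenate(parts)
    change = np.flatnonzero(np.diff(seq)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [seq.size]))
    vals = seq[starts]
    keep = vals > 0
    return vals[keep], (ends - starts)[keep]


def build_texture_matrices(labels: np.ndarray, mask: np.ndarray | None = None,
                           n_levels: int | None = None) -> TextureMatrices:
    """Build GLCM, GLRLM and GLSZM from an integer-labeled ROI.

    Parameters
    ----------
    labels : 2-D int array with levels 1..n_levels inside the ROI.
    mask : optional boolean array; defaults to ``labels > 0``.
    n_levels : number of gray levels; defaults to ``labels.max()``.
    """
    lab = np.asarray(labels, dtype=np.int64)
    if lab.ndim != 2:
        raise ValueError("labels must be 2-D")
    msk = (lab > 0) if mask is None else np.asarray(mask).astype(bool)
    lab = np.where(msk, lab, 0)
    n_pix = int(msk.sum())
    if n_pix == 0:
        raise ValueError("empty mask")
    ng = int(lab.max()) if n_levels is None else int(n_levels)
    if ng < 1:
        raise ValueError("no gray levels inside mask")

    # GLCM: symmetric, merged over the 4 directions
    glcm = np.zeros((ng, ng), dtype=np.float64)
    h, w = lab.shape
    for dr, dc in _OFFSETS:
        r0s, r0e = max(0, -dr), min(h, h - dr)
        c0s, c0e = max(0, -dc), min(w, w - dc)
        a = lab[r0s:r0e, c0s:c0e]
        b = lab[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
        ok = (a > 0) & (b > 0)
        ai, bi = a[ok] - 1, b[ok] - 1
        np.add.at(glcm, (ai, bi), 1.0)
        np.add.at(glcm, (bi, ai), 1.0)

    # GLRLM: maximal runs per direction, merged
    max_run = max(h, w)
    glrlm = np.zeros((ng, max_run), dtype=np.float64)
    for off in _OFFSETS:
        vals, lens = _run_lengths(_direction_lines(lab, off))
        np.add.at(glrlm, (vals - 1, lens - 1), 1.0)
    used = np.nonzero(glrlm.sum(axis=0))[0]
    glrlm = glrlm[:, : int(used.max()) + 1] if used.size else glrlm[:, :1]

    # GLSZM: 8-connected constant-level zones
    eight = np.ones((3, 3), dtype=int)
    zone_vals: list[int] = []
    zone_sizes: list[int] = []
    for level in np.unique(lab[msk]):
        comp, n_comp = ndimage.label(lab == level, structure=eight)
        if n_comp:
            sizes = np.bincount(comp.ravel())[1:]
            zone_vals.extend([int(level)] * n_comp)
            zone_sizes.extend(int(s) for s in sizes)
    max_zone = max(zone_sizes) if zone_sizes else 1
    glszm = np.zeros((ng, max_zone), dtype=np.float64)
    for v, s in zip(zone_vals, zone_sizes):
        glszm[v - 1, s - 1] += 1.0

    return TextureMatrices(glcm=glcm, glrlm=glrlm, glszm=glszm,
                           n_levels=ng, n_pixels=n_pix)


# ---------------------------------------------------------------------------
# Texture features

def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def glcm_features(glcm: np.ndarray) -> dict[str, float]:
    """The 25 co-occurrence features from a merged symmetric GLCM."""
    total = glcm.sum()
    if total <= 0:
        raise ValueError("empty GLCM")
    p = glcm / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    mu_x = float((i * px).sum())
    sig_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    # symmetric matrix: marginals coincide
    mu_y, sig_y = mu_x, sig_x

    diff = np.abs(ii - jj)
    # p_{x-y}(k), k = 0..ng-1
    pxmy = np.array([p[diff == k].sum() for k in range(ng)])
    k_d = np.arange(ng, dtype=np.float64)
    da = float((k_d * pxmy).sum())
    # p_{x+y}(k), k = 2..2ng
    s = ii + jj
    pxpy = np.array([p[s == k].sum() for k in range(2, 2 * ng + 1)])
    k_s = np.arange(2, 2 * ng + 1, dtype=np.float64)
    sa = float((k_s * pxpy).sum())

    hxy = _entropy2(p.ravel())
    hx = _entropy2(px)
    prod = np.outer(px, px)
    pos = p > 0
    hxy1 = float(-(p[pos] * np.log2(prod[pos])).sum()) if pos.any() else 0.0
    hxy2 = _entropy2(prod.ravel())

    # symmetric GLCM: HX == HY, so max(HX, HY) == HX
    icorr1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    icorr2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    if sig_x > 0 and sig_y > 0:
        corr = float(((ii - mu_x) * (jj - mu_y) * p).sum() / (sig_x * sig_y))
    else:
        corr = 1.0

    off = diff > 0
    inv_var = float((p[off] / diff[off] ** 2).sum()) if off.any() else 0.0

    cdev = ii + jj - mu_x - mu_y
    return {
        "F_cm.joint.max": float(p.max()),
        "F_cm.joint.avg": mu_x,
        "F_cm.joint.var": float(((ii - mu_x) ** 2 * p).sum()),
        "F_cm.joint.entr": hxy,
        "F_cm.diff.avg": da,
        "F_cm.diff.var": float(((k_d - da) ** 2 * pxmy).sum()),
        "F_cm.diff.entr": _entropy2(pxmy),
        "F_cm.sum.avg": sa,
        "F_cm.sum.var": float(((k_s - sa) ** 2 * pxpy).sum()),
        "F_cm.sum.entr": _entropy2(pxpy),
        "F_cm.energy": float((p * p).sum()),
        "F_cm.contrast": float((diff ** 2 * p).sum()),
        "F_cm.dissimilarity": float((diff * p).sum()),
        "F_cm.inv.diff": float((p / (1.0 + diff)).sum()),
        "F_cm.inv.diff.norm": float((p / (1.0 + diff / ng)).sum()),
        "F_cm.inv.diff.mom": float((p / (1.0 + diff ** 2)).sum()),
        "F_cm.inv.diff.mom.norm": float((p / (1.0 + diff ** 2 / ng ** 2)).sum()),
        "F_cm.inv.var": inv_var,
        "F_cm.corr": corr,
        "F_cm.auto.corr": float((ii * jj * p).sum()),
        "F_cm.clust.tend": float((cdev ** 2 * p).sum()),
        "F_cm.clust.shade": float((cdev ** 3 * p).sum()),
        "F_cm.clust.prom": float((cdev ** 4 * p).sum()),
        "F_cm.info.corr.1": float(icorr1),
        "F_cm.info.corr.2": icorr2,
    }


def _rl_family(m: np.ndarray, prefix: str, names: Mapping[str, str],
               perc_denom: float) -> dict[str, float]:
    """Shared run-length / size-zone feature formulas.

    ``m[i-1, j-1]`` counts runs (zones) of gray level i with length (size) j.
    """
    total = m.sum()
    if total <= 0:
        raise ValueError(f"empty {prefix} matrix")
    p = m / total
    ng, nl = p.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, nl + 1, dtype=np.float64)[None, :]
    ri = m.sum(axis=1)  # per-level counts
    rj = m.sum(axis=0)  # per-length counts
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    out = {
        names["short"]: float((p / j ** 2).sum()),
        names["long"]: float((p * j ** 2).sum()),
        names["low"]: float((p / i ** 2).sum()),
        names["high"]: float((p * i ** 2).sum()),
        names["short_low"]: float((p / (i ** 2 * j ** 2)).sum()),
        names["short_high"]: float((p * i ** 2 / j ** 2).sum()),
        names["long_low"]: float((p * j ** 2 / i ** 2).sum()),
        names["long_high"]: float((p * i ** 2 * j ** 2).sum()),
        names["glnu"]: float((ri ** 2).sum() / total),
        names["glnu_norm"]: float((ri ** 2).sum() / total ** 2),
        names["lnu"]: float((rj ** 2).sum() / total),
        names["lnu_norm"]: float((rj ** 2).sum() / total ** 2),
        names["perc"]: float(total / perc_denom),
        names["gl_var"]: float((((i - mu_i) ** 2) * p).sum()),
        names["l_var"]: float((((j - mu_j) ** 2) * p).sum()),
        names["entr"]: _entropy2(p.ravel()),
    }
    return out


_RLM_NAMES = dict(short="F_rlm.sre", long="F_rlm.lre", low="F_rlm.lgre",
                  high="F_rlm.hgre", short_low="F_rlm.srlge", short_high="F_rlm.srhge",
                  long_low="F_rlm.lrlge", long_high="F_rlm.lrhge", glnu="F_rlm.glnu",
                  glnu_norm="F_rlm.glnu.norm", lnu="F_rlm.rlnu", lnu_norm="F_rlm.rlnu.norm",
                  perc="F_rlm.r.perc", gl_var="F_rlm.gl.var", l_var="F_rlm.rl.var",
                  entr="F_rlm.rl.entr")

_SZM_NAMES = dict(short="F_szm.sze", long="F_szm.lze", low="F_szm.lgze",
                  high="F_szm.hgze", short_low="F_szm.szlge", short_high="F_szm.szhge",
                  long_low="F_szm.lzlge", long_high="F_szm.lzhge", glnu="F_szm.glu",
                  glnu_norm="F_szm.glu.norm", lnu="F_szm.zsnu", lnu_norm="F_szm.zsnu.norm",
                  perc="F_szm.z.perc", gl_var="F_szm.gl.var", l_var="F_szm.zs.var",
                  entr="F_szm.zs.entr")


def texture_features(mats: TextureMatrices) -> dict[str, float]:
    """All 57 texture features from the three matrices."""
    out = glcm_features(mats.glcm)
    out.update(_rl_family(mats.glrlm, "GLRLM", _RLM_NAMES,
                          perc_denom=mats.n_directions * mats.n_pixels))
    out.update(_rl_family(mats.glszm, "GLSZM", _SZM_NAMES, perc_denom=mats.n_pixels))
    return out


# ---------------------------------------------------------------------------
# Full extraction

def extract_roi_features(roi: NormalizedROI, n_bins: int = 32) -> dict[str, float]:
    """All 74 features from an already-normalized ROI."""
    vals = intensity_statistics(roi, n_bins=n_bins)
    labels = discretize(roi, n_bins=n_bins)
    mats = build_texture_matrices(labels, mask=roi.mask)
    vals.update(texture_features(mats))
    return vals


def extract_features(case, n_bins: int = 32, kernel: int = 3) -> FeatureVector:
    """Despeckle, normalize and extract all 74 features for one case.

    ``case`` is an :class:`adnexrad.synthetic.UltrasoundCase` or any object
    with ``image``, ``mask`` and ``case_id`` attributes.
    """
    from .preprocess import DegenerateROIError

    filtered = wiener_despeckle(case.image, kernel=kernel)
    try:
        roi = zscore_roi(filtered, case.mask, case_id=case.case_id)
    except DegenerateROIError:
        raise
    vals = extract_roi_features(roi, n_bins=n_bins)
    missing = [n for n in FEATURE_REGISTRY if n not in vals]
    if missing:  # pragma: no cover - registry is fixed
        raise RuntimeError(f"features missing from registry computation: {missing}")
    ordered = {name: float(vals[name]) for name in FEATURE_REGISTRY}
    return FeatureVector(values=ordered, case_id=case.case_id, n_bins=n_bins)


def extract_cohort_features(cases, n_bins: int = 32, kernel: int = 3):
    """Feature matrix (cases x 74 named features) for a list of cases."""
    import pandas as pd

    vecs = [extract_features(c, n_bins=n_bins, kernel=kernel) for c in cases]
    return pd.DataFrame([v.values for v in vecs],
                        index=pd.Index([v.case_id for v in vecs], name="case_id"))


class RadiomicsExtractor:
    """sklearn-style stateless transformer: cases -> 74-feature DataFrame.

    Parameters
    ----------
    n_bins : discretization bin count recorded in every feature vector.
    kernel : Wiener window size.
    """

    def __init__(self, n_bins: int = 32, kernel: int = 3):
        self.n_bins = n_bins
        self.kernel = kernel

    def get_params(self, deep: bool = True) -> dict:
        return {"n_bins": self.n_bins, "kernel": self.kernel}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in ("n_bins", "kernel"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return extract_cohort_features(X, n_bins=self.n_bins, kernel=self.kernel)
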