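"""Synthetic ultrasound cohort generator.

Generates image + mask + clinical-covariate cohorts with the statistical
structure the downstream analysis assumes, so the whole pipeline is testable
without any clinical data:

* five histology strata (benign, borderline, FIGO stage I-II, stage III-IV,
  metastasis) with a configurable mix; the default mix reproduces a cohort
  that is ~61% benign / ~39% malignant with the malignant substrata in
  realistic proportions;
* speckle-textured lesions: each image is a smooth echo field multiplied by
  gamma-distributed speckle (fully-developed-speckle approximation, shape 4),
  with an elliptical hypoechoic lesion ROI; malignant strata receive
  additional mixed low/high-intensity blobs inside the ROI, raising intensity
  kurtosis and gray-level non-uniformity by a configurable effect size;
* age and log-CA125 drawn from class-shifted distributions, CA125 masked
  missing completely at random at a configurable rate (default 25%);
* a categorical "manufacturer" tag applied as a mild global gain/offset,
  which per-ROI Z-scoring removes exactly.

The generator emulates which *features move* between classes, not acoustic
physics; see docs/methods.md for what that does and does not validate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

STRATA = ("benign", "borderline", "stage_I_II", "stage_III_IV", "metastasis")

#: Default class mix: benign 1270, borderline 113, stage I-II 268,
#: stage III-IV 325, metastasis 97 out of 2073 (61.3% / 38.7% malignant).
DEFAULT_CLASS_MIX = (1270 / 2073, 113 / 2073, 268 / 2073, 325 / 2073, 97 / 2073)

#: Relative strength of the malignancy signal per malignant stratum
#: (borderline masses are the mildest, advanced disease the strongest).
_STRATUM_WEIGHT = {"borderline": 0.6, "stage_I_II": 0.85,
                   "stage_III_IV": 1.0, "metastasis": 0.9}

#: Internal scale mapping effect_sizes.texture = 1.0 to the calibrated
#: default separability (see scripts/calibrate_generator.py).
_TEXTURE_SCALE = 0.3

#: Validation AUC the default generator settings are designed to reach for a
#: radiomics-only model, established once by the calibration simulation in
#: scripts/calibrate_generator.py (see docs/methods.md).
DESIGN_TARGET_AUC = 0.814


def is_malignant(label: str) -> bool:
    if label not in STRATA:
        raise ValueError(f"unknown outcome label {label!r}; admissible: {list(STRATA)}")
    return label != "benign"


@dataclass
class EffectSizes:
    """Per-axis class-separation strengths (multipliers on the built-in
    per-stratum weights). 1.0 is the calibrated default condition; 0 removes
    the corresponding signal entirely."""

    texture: float = 1.0
    age: float = 1.0
    ca125: float = 1.0


@dataclass
class CohortSpec:
    """Configuration of a synthetic cohort."""

    n_cases: int = 400
    class_mix: tuple[float, ...] = DEFAULT_CLASS_MIX
    ca125_missing_rate: float = 0.25
    effect_sizes: EffectSizes = field(default_factory=EffectSizes)
    n_manufacturers: int = 3
    seed: int = 0
    image_size: int = 96

    def validate(self) -> None:
        if self.n_cases < 10:
            raise ValueError("n_cases must be >= 10 (smaller cohorts make the "
                             "stratified split degenerate)")
        mix = np.asarray(self.class_mix, dtype=float)
        if mix.size != len(STRATA) or (mix < 0).any() or (mix > 1).any():
            raise ValueError("class_mix must be 5 probabilities in [0, 1]")
        if abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if not 0.0 <= self.ca125_missing_rate <= 1.0:
            raise ValueError("ca125_missing_rate must be in [0, 1]")
        if self.n_manufacturers < 1:
            raise ValueError("need at least one manufacturer")
        if self.image_size < 32:
            raise ValueError("image_size too small for a >= 32-pixel ROI")


@dataclass
class UltrasoundCase:
    """One synthetic examination: image, lesion mask and clinical covariates."""

    case_id: str
    image: np.ndarray        # uint8, 2-D
    mask: np.ndarray         # bool, 2-D, same shape
    age: float               # years
    ca125: float | None      # U/mL, None when missing
    manufacturer: str
    outcome: str             # one of STRATA
    subjective_malignant: bool | None = None

    @property
    def malignant(self) -> bool:
        return is_malignant(self.outcome)

    def validate(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError(f"{self.case_id}: image/mask shape mismatch")
        if int(self.mask.sum()) < 32:
            raise ValueError(f"{self.case_id}: mask has < 32 foreground pixels")
        if not self.age > 0:
            raise ValueError(f"{self.case_id}: age must be positive")
        if self.ca125 is not None and not self.ca125 > 0:
            raise ValueError(f"{self.case_id}: CA125 must be positive when present")
        is_malignant(self.outcome)


def _ellipse_mask(size: int, rng: np.random.Generator) -> np.ndarray:
    """Random rotated ellipse well inside the frame, >= 32 pixels."""
    cy = size / 2 + rng.uniform(-size * 0.08, size * 0.08)
    cx = size / 2 + rng.uniform(-size * 0.08, size * 0.08)
    a = rng.uniform(size * 0.14, size * 0.30)
    b = rng.uniform(size * 0.14, size * 0.30)
    theta = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _smooth_field(size: int, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency echo background in [0.8, 1.2] (relative units)."""
    f = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=size / 8)
    span = f.max() - f.min()
    if span > 0:
        f = (f - f.min()) / span
    return 0.8 + 0.4 * f


def _render_case(stratum: str, eff: EffectSizes, size: int,
                 gain: float, offset: float, speckle_shape: float,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    mask = _ellipse_mask(size, rng)
    base = 130.0 * _smooth_field(size, rng)
    # lesion is hypoechoic relative to surrounding tissue
    tissue = np.where(mask, base * 0.6, base)

    if stratum != "benign" and eff.texture > 0:
        w = _STRATUM_WEIGHT[stratum] * eff.texture * _TEXTURE_SCALE
        n_blobs = int(rng.integers(2, 4 + max(1, round(4 * w))))
        ys, xs = np.nonzero(mask)
        yy, xx = np.mgrid[0:size, 0:size]
        for _ in range(n_blobs):
            k = rng.integers(0, ys.size)
            r = rng.uniform(1.5, 2.0 + 3.0 * w)
            amp = rng.uniform(35.0, 45.0 + 40.0 * w)
            sign = 1.0 if rng.random() < 0.5 else -0.55
            blob = np.exp(-(((yy - ys[k]) ** 2 + (xx - xs[k]) ** 2) / (2 * r * r)))
            tissue = tissue + sign * amp * blob * mask

    speckle = rng.gamma(shape=speckle_shape, scale=1.0 / speckle_shape,
                        size=(size, size))
    img = np.clip(tissue, 5.0, None) * speckle
    img = img * gain + offset
    return np.clip(img, 0, 255).astype(np.uint8), mask


def generate_cohort(spec: CohortSpec, speckle_shape: float = 4.0) -> list[UltrasoundCase]:
    """Generate a deterministic synthetic cohort from a single RNG stream."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mix = np.asarray(spec.class_mix, dtype=float)
    eff = spec.effect_sizes

    manufacturers = [f"vendor_{chr(ord('A') + m)}" for m in range(spec.n_manufacturers)]
    # mild, vendor-specific global affine intensity transform
    gains = [0.9 + 0.2 * m / max(1, spec.n_manufacturers - 1)
             for m in range(spec.n_manufacturers)]
    offsets = [-6.0 + 12.0 * m / max(1, spec.n_manufacturers - 1)
               for m in range(spec.n_manufacturers)]

    age_shift = {"benign": 0.0, "borderline": 1.0, "stage_I_II": 6.0,
                 "stage_III_IV": 12.0, "metastasis": 8.0}
    logca_shift = {"benign": 0.0, "borderline": 0.7, "stage_I_II": 1.2,
                   "stage_III_IV": 2.4, "metastasis": 1.5}

    cases: list[UltrasoundCase] = []
    for k in range(spec.n_cases):
        stratum = STRATA[int(rng.choice(len(STRATA), p=mix))]
        m = int(rng.integers(0, spec.n_manufacturers))
        image, mask = _render_case(stratum, eff, spec.image_size,
                                   gains[m], offsets[m], speckle_shape, rng)
        age = float(np.clip(rng.normal(48.0 + eff.age * age_shift[stratum], 13.0),
                            18.0, 95.0))
        log_ca = rng.normal(np.log(20.0) + eff.ca125 * logca_shift[stratum], 0.9)
        ca125: float | None = float(np.exp(log_ca))
        if rng.random() < spec.ca125_missing_rate:
            ca125 = None
        if stratum == "benign":
            subj = bool(rng.random() < 0.14)   # 1 - specificity of expert assessment
        else:
            subj = bool(rng.random() < 0.96)   # sensitivity of expert assessment
        case = UltrasoundCase(
            case_id=f"case_{k:05d}", image=image, mask=mask, age=age,
            ca125=ca125, manufacturer=manufacturers[m], outcome=stratum,
            subjective_malignant=subj,
        )
        case.validate()
        cases.append(case)
    return cases


# ---------------------------------------------------------------------------
# ADNEX predictor synthesis (the image generator produces no diameters; the
# ultrasound morphology predictors are sampled conditionally on the outcome)

def generate_adnex_inputs(cases: list[UltrasoundCase], seed: int = 0) -> pd.DataFrame:
    """Sample ADNEX ultrasound predictors conditionally on each case's outcome.

    Returns a DataFrame aligned with ``cases`` (index = case_id) holding the
    nine ADNEX predictors. Effects are deliberately strong so that, by
    construction, a correctly implemented ADNEX-style model separates classes
    well on this cohort.
    """
    rng = np.random.default_rng(seed)
    solid_beta = {"benign": (1.0, 6.0), "borderline": (2.5, 3.0),
                  "stage_I_II": (4.0, 2.0), "stage_III_IV": (6.0, 1.5),
                  "metastasis": (8.0, 1.2)}
    pap_p = {"benign": 0.10, "borderline": 0.55, "stage_I_II": 0.40,
             "stage_III_IV": 0.30, "metastasis": 0.15}
    ascites_p = {"benign": 0.03, "borderline": 0.08, "stage_I_II": 0.15,
                 "stage_III_IV": 0.55, "metastasis": 0.35}
    shadow_p = {"benign": 0.28, "borderline": 0.10, "stage_I_II": 0.08,
                "stage_III_IV": 0.05, "metastasis": 0.05}
    diam_shift = {"benign": 0.0, "borderline": 0.25, "stage_I_II": 0.35,
                  "stage_III_IV": 0.30, "metastasis": 0.15}
    rows = []
    for c in cases:
        s = c.outcome
        a, b = solid_beta[s]
        solid = float(rng.beta(a, b))
        if s == "benign" and rng.random() < 0.5:
            solid = 0.0  # purely cystic benign masses
        rows.append({
            "case_id": c.case_id,
            "age": c.age,
            "ca125": c.ca125,
            "max_lesion_diameter": float(np.exp(rng.normal(np.log(66.0) + diam_shift[s], 0.45))),
            "proportion_solid": min(solid, 1.0),
            "more_than_10_locules": bool(rng.random() < 0.13),
            "n_papillary_projections": int(rng.binomial(4, pap_p[s])),
            "acoustic_shadows": bool(rng.random() < shadow_p[s]),
            "ascites": bool(rng.random() < ascites_p[s]),
            "oncology_center": True,
        })
    return pd.DataFrame(rows).set_index("case_id")


# ---------------------------------------------------------------------------
# Disk round-trip (PNG images/masks + CSV clinical table + JSON manifest)

CLINICAL_COLUMNS = ["case_id", "age", "ca125", "manufacturer", "outcome",
                    "subjective_malignant"]


def write_cohort(cohort: list[UltrasoundCase], directory: str | Path) -> Path:
    """Write a cohort to ``directory``; returns the manifest path.

    Layout: ``images/<case_id>.png`` (8-bit grayscale), ``masks/<case_id>.png``
    (binary, 0/255), ``clinical.csv`` and ``manifest.json``.
    """
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    (directory / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for c in cohort:
        c.validate()
        Image.fromarray(c.image, mode="L").save(directory / "images" / f"{c.case_id}.png")
        Image.fromarray((c.mask.astype(np.uint8) * 255), mode="L").save(
            directory / "masks" / f"{c.case_id}.png")
        rows.append({
            "case_id": c.case_id,
            "age": repr(float(c.age)),
            "ca125": "" if c.ca125 is None else repr(float(c.ca125)),
            "manufacturer": c.manufacturer,
            "outcome": c.outcome,
            "subjective_malignant": ("" if c.subjective_malignant is None
                                     else str(bool(c.subjective_malignant))),
        })
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(directory / "clinical.csv", index=False)
    manifest = {
        "format_version": 1,
        "n_cases": len(cohort),
        "case_ids": [c.case_id for c in cohort],
        "clinical_table": "clinical.csv",
        "columns": CLINICAL_COLUMNS,
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_cohort(directory: str | Path) -> list[UltrasoundCase]:
    """Read a cohort written by :func:`write_cohort`.

    A missing mask (or image) raises a hard error naming the case; an unknown
    outcome label raises an error listing the admissible labels.
    """
    directory = Path(directory)
    table = pd.read_csv(directory / "clinical.csv", dtype=str, keep_default_na=False)
    cases: list[UltrasoundCase] = []
    for _, row in table.iterrows():
        cid = row["case_id"]
        img_path = directory / "images" / f"{cid}.png"
        mask_path = directory / "masks" / f"{cid}.png"
        if not img_path.exists():
            raise FileNotFoundError(f"image missing for case {cid!r}: {img_path}")
        if not mask_path.exists():
            raise FileNotFoundError(f"mask missing for case {cid!r}: {mask_path}")
        outcome = row["outcome"]
        is_malignant(outcome)  # validates the label
        subj_raw = row["subjective_malignant"]
        cases.append(UltrasoundCase(
            case_id=cid,
            image=np.asarray(Image.open(img_path), dtype=np.uint8),
            mask=np.asarray(Image.open(mask_path)) > 127,
            age=float(row["age"]),
            ca125=None if row["ca125"] == "" else float(row["ca125"]),
            manufacturer=row["manufacturer"],
            outcome=outcome,
            subjective_malignant=None if subj_raw == "" else subj_raw == "True",
        ))
    return cases


def cohort_clinical_frame(cohort: list[UltrasoundCase]) -> pd.DataFrame:
    """Clinical covariates and outcome as a DataFrame (index = case_id)."""
    return pd.DataFrame({
        "age": [c.age for c in cohort],
        "ca125": [np.nan if c.ca125 is None else c.ca125 for c in cohort],
        "manufacturer": [c.manufacturer for c in cohort],
        "outcome": [c.outcome for c in cohort],
        "malignant": [int(c.malignant) for c in cohort],
        "subjective_malignant": [c.subjective_malignant for c in cohort],
    }, index=pd.Index([c.case_id for c in cohort], name="case_id"))
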