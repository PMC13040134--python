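"""ADNEX-style multinomial risk calculator (the study comparator).

ADNEX (Assessment of Different NEoplasias in the adneXa) estimates, from
three clinical and six ultrasound predictors, the probabilities that an
adnexal mass is benign, borderline, stage I invasive, stage II-IV invasive
or a metastasis, via a multinomial logistic model with the benign class as
reference; the overall risk of malignancy is 1 - P(benign). Two coefficient
variants exist, with and without serum CA 125.

The coefficients are read from a bundled human-readable JSON file rather
than being hard-coded. The bundled file is a clearly labelled SYNTHETIC
stand-in that reproduces the model's structure and coefficient signs (see
the file's own header); load a transcription of the published coefficient
tables with :func:`load_coefficients` for clinical use.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

_CLASS_KEYS = ("borderline", "stage_I", "stage_II_IV", "metastatic")


@dataclass
class AdnexInput:
    """Predictors of the ADNEX model for one mass."""

    age: float                       # years
    max_lesion_diameter: float       # mm
    proportion_solid: float          # fraction of max diameter, [0, 1]
    more_than_10_locules: bool
    n_papillary_projections: int     # 0..4
    acoustic_shadows: bool
    ascites: bool
    oncology_center: bool
    ca125: float | None = None       # U/mL, None when missing

    def validate(self) -> None:
        if not self.age > 0:
            raise ValueError("age must be positive")
        if not self.max_lesion_diameter > 0:
            raise ValueError("max_lesion_diameter must be positive")
        if not 0.0 <= self.proportion_solid <= 1.0:
            raise ValueError("proportion_solid must be in [0, 1]")
        if not 0 <= int(self.n_papillary_projections) <= 4:
            raise ValueError("n_papillary_projections must be on the 0-4 scale")
        if self.ca125 is not None and not self.ca125 > 0:
            raise ValueError("ca125 must be positive when present")


@dataclass
class AdnexRisks:
    """Per-class probabilities; risk_malignant = 1 - p_benign."""

    p_benign: float
    p_borderline: float
    p_stage_I: float
    p_stage_II_IV: float
    p_metastatic: float

    @property
    def risk_malignant(self) -> float:
        return 1.0 - self.p_benign

    def as_dict(self) -> dict[str, float]:
        return {"p_benign": self.p_benign, "p_borderline": self.p_borderline,
                "p_stage_I": self.p_stage_I, "p_stage_II_IV": self.p_stage_II_IV,
                "p_metastatic": self.p_metastatic,
                "risk_malignant": self.risk_malignant}


def load_coefficients(path: str | Path | None = None) -> dict:
    """Load a coefficient file; defaults to the bundled synthetic stand-in."""
    if path is None:
        ref = resources.files("adnexrad.data") / "adnex_coefficients_synthetic.json"
        coeffs = json.loads(ref.read_text())
    else:
        coeffs = json.loads(Path(path).read_text())
    for key in ("predictors", "with_ca125", "without_ca125", "classes"):
        if key not in coeffs:
            raise ValueError(f"coefficient file lacks required key {key!r}")
    return coeffs


def _transform(value: float, transform: str) -> float:
    if transform == "identity":
        return float(value)
    if transform == "log2":
        if value <= 0:
            raise ValueError("log2 transform requires a positive value")
        return math.log2(value)
    raise ValueError(f"unknown transform {transform!r}")


def adnex_risk(inp: AdnexInput, use_ca125: bool = True,
               coefficients: dict | None = None) -> AdnexRisks:
    """Five-class risks for one mass via the multinomial-logistic softmax."""
    inp.validate()
    if use_ca125 and inp.ca125 is None:
        raise ValueError("use_ca125=True but ca125 is missing")
    coeffs = coefficients if coefficients is not None else load_coefficients()
    table = coeffs["with_ca125"] if use_ca125 else coeffs["without_ca125"]
    raw = {
        "age": inp.age, "oncology_center": float(bool(inp.oncology_center)),
        "ca125": inp.ca125, "max_lesion_diameter": inp.max_lesion_diameter,
        "proportion_solid": inp.proportion_solid,
        "more_than_10_locules": float(bool(inp.more_than_10_locules)),
        "n_papillary_projections": float(inp.n_papillary_projections),
        "acoustic_shadows": float(bool(inp.acoustic_shadows)),
        "ascites": float(bool(inp.ascites)),
    }
    values: dict[str, float] = {}
    for pred in coeffs["predictors"]:
        if pred["name"] == "log2_ca125" and not use_ca125:
            continue
        values[pred["name"]] = _transform(raw[pred["source"]], pred["transform"])
    zs = []
    for cls in _CLASS_KEYS:
        beta = table[cls]
        z = beta["intercept"] + sum(beta[name] * v for name, v in values.items()
                                    if name in beta)
        zs.append(z)
    # softmax with the benign reference class at z = 0
    z_all = np.array([0.0] + zs)
    z_all -= z_all.max()
    e = np.exp(z_all)
    p = e / e.sum()
    return AdnexRisks(p_benign=float(p[0]), p_borderline=float(p[1]),
                      p_stage_I=float(p[2]), p_stage_II_IV=float(p[3]),
                      p_metastatic=float(p[4]))


def adnex_risk_frame(inputs: pd.DataFrame, coefficients: dict | None = None) -> pd.DataFrame:
    """Risks for a table of ADNEX inputs (one row per case).

    The CA125 variant is used whenever a case's CA125 is available, the
    without-CA125 variant otherwise — mirroring the comparator's usage.
    """
    rows = {}
    for cid, row in inputs.iterrows():
        ca = row.get("ca125")
        ca = None if (ca is None or (isinstance(ca, float) and np.isnan(ca))) else float(ca)
        inp = AdnexInput(
            age=float(row["age"]), max_lesion_diameter=float(row["max_lesion_diameter"]),
            proportion_solid=float(row["proportion_solid"]),
            more_than_10_locules=bool(row["more_than_10_locules"]),
            n_papillary_projections=int(row["n_papillary_projections"]),
            acoustic_shadows=bool(row["acoustic_shadows"]),
            ascites=bool(row["ascites"]), oncology_center=bool(row["oncology_center"]),
            ca125=ca)
        risks = adnex_risk(inp, use_ca125=ca is not None, coefficients=coefficients)
        rows[cid] = risks.as_dict()
    return pd.DataFrame.from_dict(rows, orient="index")


def compare_models(risks_by_model: dict[str, np.ndarray], labels,
                   cutoffs: dict[str, float] | None = None,
                   seed: int = 0, n_boot: int = 2000) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluation battery rows per model plus pairwise DeLong comparisons.

    Returns ``(metrics_table, delong_table)``. ``cutoffs`` maps model name to
    a probability cutoff (default 0.10 everywhere). Risk vectors must be
    predictions for the same case set.
    """
    from .evaluation import auc, delong_compare, metrics_at_cutoff

    labels = np.asarray(labels).astype(int)
    sizes = {name: np.asarray(r).size for name, r in risks_by_model.items()}
    if len(set(sizes.values())) > 1 or labels.size not in set(sizes.values()):
        raise ValueError(f"case sets differ across models: {sizes}")
    cutoffs = cutoffs or {}
    rows = []
    for name, r in risks_by_model.items():
        point, ci = auc(r, labels, seed=seed, n_boot=n_boot)
        met = metrics_at_cutoff(r, labels, cutoffs.get(name, 0.10))
        row = {"model": name, "auc": point, "auc_lo": ci[0], "auc_hi": ci[1]}
        row.update(met.as_row())
        rows.append(row)
    names = list(risks_by_model)
    drows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            p, z = delong_compare(risks_by_model[a], risks_by_model[b], labels)
            drows.append({"model_a": a, "model_b": b, "delong_p": p, "delong_z": z})
    return pd.DataFrame(rows), pd.DataFrame(drows)
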