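{
  "_comment": [
    "SYNTHETIC stand-in coefficient set for an ADNEX-style multinomial",
    "logistic risk calculator. The structure (benign reference class, four",
    "malignant classes, nine predictors, log2 transforms of CA125 and the",
    "maximal lesion diameter) follows the published ADNEX model; the",
    "numerical values here are NOT the published coefficients - they are",
    "sign-correct plausible values chosen so that all structural properties",
    "(probability simplex, per-predictor monotonicity) hold. Replace this",
    "file with a transcription of the original publication's coefficient",
    "tables for clinical use."
  ],
  "reference_class": "benign",
  "classes": ["borderline", "stage_I", "stage_II_IV", "metastatic"],
  "predictors": [
    {"name": "age", "source": "age", "transform": "identity"},
    {"name": "oncology_center", "source": "oncology_center", "transform": "identity"},
    {"name": "log2_ca125", "source": "ca125", "transform": "log2"},
    {"name": "log2_max_diameter", "source": "max_lesion_diameter", "transform": "log2"},
    {"name": "proportion_solid", "source": "proportion_solid", "transform": "identity"},
    {"name": "more_than_10_locules", "source": "more_than_10_locules", "transform": "identity"},
    {"name": "n_papillary_projections", "source": "n_papillary_projections", "transform": "identity"},
    {"name": "acoustic_shadows", "source": "acoustic_shadows", "transform": "identity"},
    {"name": "ascites", "source": "ascites", "transform": "identity"}
  ],
  "with_ca125": {
    "borderline": {
      "intercept": -7.0, "age": 0.015, "oncology_center": 0.3,
      "log2_ca125": 0.2, "log2_max_diameter": 0.45, "proportion_solid": 2.1,
      "more_than_10_locules": 0.3, "n_papillary_projections": 0.55,
      "acoustic_shadows": -1.0, "ascites": 0.4
    },
    "stage_I": {
      "intercept": -9.0, "age": 0.03, "oncology_center": 0.5,
      "log2_ca125": 0.35, "log2_max_diameter": 0.6, "proportion_solid": 3.2,
      "more_than_10_locules": 0.2, "n_papillary_projections": 0.35,
      "acoustic_shadows": -1.2, "ascites": 0.8
    },
    "stage_II_IV": {
      "intercept": -12.0, "age": 0.045, "oncology_center": 0.7,
      "log2_ca125": 0.7, "log2_max_diameter": 0.5, "proportion_solid": 4.0,
      "more_than_10_locules": 0.1, "n_papillary_projections": 0.25,
      "acoustic_shadows": -1.6, "ascites": 1.6
    },
    "metastatic": {
      "intercept": -10.5, "age": 0.04, "oncology_center": 0.4,
      "log2_ca125": 0.4, "log2_max_diameter": 0.35, "proportion_solid": 3.6,
      "more_than_10_locules": 0.4, "n_papillary_projections": 0.1,
      "acoustic_shadows": -1.4, "ascites": 1.1
    }
  },
  "without_ca125": {
    "borderline": {
      "intercept": -6.2, "age": 0.015, "oncology_center": 0.3,
      "log2_max_diameter": 0.45, "proportion_solid": 2.1,
      "more_than_10_locules": 0.3, "n_papillary_projections": 0.55,
      "acoustic_shadows": -1.0, "ascites": 0.4
    },
    "stage_I": {
      "intercept": -7.6, "age": 0.03, "oncology_center": 0.5,
      "log2_max_diameter": 0.6, "proportion_solid": 3.2,
      "more_than_10_locules": 0.2, "n_papillary_projections": 0.35,
      "acoustic_shadows": -1.2, "ascites": 0.8
    },
    "stage_II_IV": {
      "intercept": -9.2, "age": 0.045, "oncology_center": 0.7,
      "log2_max_diameter": 0.5, "proportion_solid": 4.0,
      "more_than_10_locules": 0.1, "n_papillary_projections": 0.25,
      "acoustic_shadows": -1.6, "ascites": 1.6
    },
    "metastatic": {
      "intercept": -8.9, "age": 0.04, "oncology_center": 0.4,
      "log2_max_diameter": 0.35, "proportion_solid": 3.6,
      "more_than_10_locules": 0.4, "n_papillary_projections": 0.1,
      "acoustic_shadows": -1.4, "ascites": 1.1
    }
  }
}
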