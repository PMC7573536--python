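{
  "$defs": {
    "DesignConfig": {
      "additionalProperties": false,
      "description": "Run structure: fixation, then alternating mini-block pairs.",
      "properties": {
        "fcnf_len": {
          "default": 20,
          "minimum": 1,
          "title": "Fcnf Len",
          "type": "integer"
        },
        "fixation_len": {
          "default": 20,
          "minimum": 0,
          "title": "Fixation Len",
          "type": "integer"
        },
        "n_pairs": {
          "default": 7,
          "minimum": 0,
          "title": "N Pairs",
          "type": "integer"
        },
        "n_runs": {
          "default": 4,
          "minimum": 1,
          "title": "N Runs",
          "type": "integer"
        },
        "nonf_len": {
          "default": 20,
          "minimum": 1,
          "title": "Nonf Len",
          "type": "integer"
        },
        "start_condition": {
          "default": "fcnf",
          "enum": [
            "fcnf",
            "nonf"
          ],
          "title": "Start Condition",
          "type": "string"
        }
      },
      "title": "DesignConfig",
      "type": "object"
    },
    "FeedbackSettings": {
      "additionalProperties": false,
      "properties": {
        "frozen_segment": {
          "default": 6,
          "minimum": 1,
          "title": "Frozen Segment",
          "type": "integer"
        },
        "implementation": {
          "default": "weighted_negative",
          "enum": [
            "negative",
            "weighted_negative",
            "positive"
          ],
          "title": "Implementation",
          "type": "string"
        },
        "n_segments": {
          "default": 10,
          "minimum": 1,
          "title": "N Segments",
          "type": "integer"
        },
        "upper_bound": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Upper Bound"
        },
        "window_length": {
          "default": 20,
          "minimum": 3,
          "title": "Window Length",
          "type": "integer"
        }
      },
      "title": "FeedbackSettings",
      "type": "object"
    },
    "SimulateSettings": {
      "additionalProperties": false,
      "description": "Cohort generator settings; see ``fcnf.simulate.CohortParams``.",
      "properties": {
        "ar_coef": {
          "default": 0.3,
          "exclusiveMaximum": 1,
          "minimum": 0,
          "title": "Ar Coef",
          "type": "number"
        },
        "counterbalance": {
          "default": true,
          "title": "Counterbalance",
          "type": "boolean"
        },
        "delta_mean": {
          "default": -0.15,
          "title": "Delta Mean",
          "type": "number"
        },
        "delta_noise_sd": {
          "default": 0.04,
          "minimum": 0,
          "title": "Delta Noise Sd",
          "type": "number"
        },
        "drift_mean": {
          "default": -0.01,
          "title": "Drift Mean",
          "type": "number"
        },
        "drift_sd": {
          "default": 0.015,
          "exclusiveMinimum": 0,
          "title": "Drift Sd",
          "type": "number"
        },
        "gamma": {
          "default": 0.5,
          "minimum": 0,
          "title": "Gamma",
          "type": "number"
        },
        "link_stais_delta": {
          "default": 0.04,
          "title": "Link Stais Delta",
          "type": "number"
        },
        "link_stait_rho": {
          "default": 0.08,
          "title": "Link Stait Rho",
          "type": "number"
        },
        "link_tcaq_rho": {
          "default": -0.08,
          "title": "Link Tcaq Rho",
          "type": "number"
        },
        "link_xw_delta": {
          "default": -0.035,
          "title": "Link Xw Delta",
          "type": "number"
        },
        "link_xwz_delta": {
          "default": 0.04,
          "title": "Link Xwz Delta",
          "type": "number"
        },
        "n_subjects": {
          "default": 20,
          "minimum": 2,
          "title": "N Subjects",
          "type": "integer"
        },
        "noise_sd": {
          "default": 1.0,
          "exclusiveMinimum": 0,
          "title": "Noise Sd",
          "type": "number"
        },
        "rho_base_mean": {
          "default": 0.15,
          "title": "Rho Base Mean",
          "type": "number"
        },
        "rho_noise_sd": {
          "default": 0.08,
          "minimum": 0,
          "title": "Rho Noise Sd",
          "type": "number"
        }
      },
      "title": "SimulateSettings",
      "type": "object"
    },
    "StatsSettings": {
      "additionalProperties": false,
      "properties": {
        "bootstrap_b": {
          "default": 1000,
          "minimum": 100,
          "title": "Bootstrap B",
          "type": "integer"
        },
        "correction": {
          "default": "none",
          "enum": [
            "none",
            "bh"
          ],
          "title": "Correction",
          "type": "string"
        },
        "fisher_variant": {
          "default": "z",
          "enum": [
            "z",
            "t"
          ],
          "title": "Fisher Variant",
          "type": "string"
        },
        "outlier_threshold": {
          "anyOf": [
            {
              "exclusiveMinimum": 0,
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Outlier Threshold"
        },
        "slope_scope": {
          "default": "all",
          "enum": [
            "all",
            "fcnf_only",
            "nonf_only"
          ],
          "title": "Slope Scope",
          "type": "string"
        }
      },
      "title": "StatsSettings",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "properties": {
    "design": {
      "$ref": "#/$defs/DesignConfig",
      "default": {
        "fcnf_len": 20,
        "fixation_len": 20,
        "n_pairs": 7,
        "n_runs": 4,
        "nonf_len": 20,
        "start_condition": "fcnf"
      }
    },
    "feedback": {
      "$ref": "#/$defs/FeedbackSettings",
      "default": {
        "frozen_segment": 6,
        "implementation": "weighted_negative",
        "n_segments": 10,
        "upper_bound": null,
        "window_length": 20
      }
    },
    "seed": {
      "default": 0,
      "title": "Seed",
      "type": "integer"
    },
    "simulate": {
      "$ref": "#/$defs/SimulateSettings",
      "default": {
        "ar_coef": 0.3,
        "counterbalance": true,
        "delta_mean": -0.15,
        "delta_noise_sd": 0.04,
        "drift_mean": -0.01,
        "drift_sd": 0.015,
        "gamma": 0.5,
        "link_stais_delta": 0.04,
        "link_stait_rho": 0.08,
        "link_tcaq_rho": -0.08,
        "link_xw_delta": -0.035,
        "link_xwz_delta": 0.04,
        "n_subjects": 20,
        "noise_sd": 1.0,
        "rho_base_mean": 0.15,
        "rho_noise_sd": 0.08
      }
    },
    "stats": {
      "$ref": "#/$defs/StatsSettings",
      "default": {
        "bootstrap_b": 1000,
        "correction": "none",
        "fisher_variant": "z",
        "outlier_threshold": null,
        "slope_scope": "all"
      }
    }
  },
  "title": "PipelineConfig",
  "type": "object"
}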