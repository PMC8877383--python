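{
  "name": "initial",
  "description": "Initial study cohort (n=205): angiography patients stratified by Gensini score as atherosclerosis-free (GS=0), subclinical (0<GS<35) and severe (GS>=35). Blood-marker parameters ('reported') follow the published per-stratum summaries; the subclinical stratum reuses the GS<35 column, which it dominates. Carotid-imaging parameters are not published per stratum and are synthetic calibration values ('synthetic') chosen to give a severity-graded ultrasound sub-score.",
  "n_strata": {"free": 39, "subclinical": 73, "severe": 93},
  "variables": {
    "age": {
      "family": "normal", "provenance": "reported", "truncate": [18, null],
      "params": {
        "free": {"mean": 62.8, "sd": 9.0},
        "subclinical": {"mean": 62.8, "sd": 9.0},
        "severe": {"mean": 62.8, "sd": 9.0}
      }
    },
    "sex": {
      "family": "bernoulli", "provenance": "reported", "category": "male",
      "params": {
        "free": {"p": 0.66},
        "subclinical": {"p": 0.66},
        "severe": {"p": 0.66}
      }
    },
    "tc": {
      "family": "normal", "provenance": "reported", "truncate": [0, null],
      "params": {
        "free": {"mean": 5.5, "sd": 1.3},
        "subclinical": {"mean": 5.2, "sd": 1.2},
        "severe": {"mean": 5.1, "sd": 1.3}
      }
    },
    "ldl_c": {
      "family": "normal", "provenance": "reported", "truncate": [0, null],
      "params": {
        "free": {"mean": 3.7, "sd": 1.3},
        "subclinical": {"mean": 3.3, "sd": 1.0},
        "severe": {"mean": 3.2, "sd": 1.2}
      }
    },
    "hdl_c": {
      "family": "normal", "provenance": "reported", "truncate": [0, null],
      "params": {
        "free": {"mean": 1.1, "sd": 0.3},
        "subclinical": {"mean": 1.0, "sd": 0.3},
        "severe": {"mean": 1.0, "sd": 0.3}
      }
    },
    "tg": {
      "family": "lognormal", "provenance": "reported", "truncate": [0, null],
      "params": {
        "free": {"median": 1.6, "q25": 1.2, "q75": 2.1},
        "subclinical": {"median": 1.6, "q25": 1.2, "q75": 2.1},
        "severe": {"median": 1.6, "q25": 1.2, "q75": 2.2}
      }
    },
    "apo_ai": {
      "family": "normal", "provenance": "reported", "truncate": [0, null],
      "params": {
        "free": {"mean": 1.70, "sd": 0.29},
        "subclinical": {"mean": 1.60, "sd": 0.32},
        "severe": {"mean": 1.54, "sd": 0.25}
      }
    },
    "apo_b": {
      "family": "normal", "provenance": "reported", "truncate": [0, null],
      "params": {
        "free": {"mean": 1.02, "sd": 0.24},
        "subclinical": {"mean": 0.95, "sd": 0.23},
        "severe": {"mean": 0.87, "sd": 0.26}
      }
    },
    "hscrp": {
      "family": "lognormal", "provenance": "reported", "truncate": [0, null],
      "params": {
        "free": {"median": 2.8, "q25": 1.1, "q75": 5.7},
        "subclinical": {"median": 2.4, "q25": 1.1, "q75": 5.1},
        "severe": {"median": 3.3, "q25": 1.5, "q75": 6.6}
      }
    },
    "fibrinogen": {
      "family": "lognormal", "provenance": "reported", "truncate": [0, null],
      "params": {
        "free": {"median": 3.7, "q25": 3.2, "q75": 4.1},
        "subclinical": {"median": 3.6, "q25": 3.2, "q75": 4.1},
        "severe": {"median": 3.7, "q25": 3.3, "q75": 4.2}
      }
    },
    "glucose": {
      "family": "normal", "provenance": "reported", "truncate": [0, null],
      "params": {
        "free": {"mean": 5.7, "sd": 1.1},
        "subclinical": {"mean": 5.9, "sd": 1.5},
        "severe": {"mean": 6.0, "sd": 1.4}
      }
    },
    "insulin": {
      "family": "lognormal", "provenance": "reported", "truncate": [0, null],
      "params": {
        "free": {"median": 10.1, "q25": 7.4, "q75": 15.0},
        "subclinical": {"median": 10.2, "q25": 7.2, "q75": 14.3},
        "severe": {"median": 10.7, "q25": 7.5, "q75": 14.9}
      }
    },
    "adiponectin": {
      "family": "lognormal", "provenance": "reported", "truncate": [0, null],
      "params": {
        "free": {"median": 9.2, "q25": 7.1, "q75": 11.8},
        "subclinical": {"median": 8.0, "q25": 5.8, "q75": 11.8},
        "severe": {"median": 7.8, "q25": 5.5, "q75": 11.4}
      }
    },
    "leptin": {
      "family": "lognormal", "provenance": "reported", "truncate": [0, null],
      "params": {
        "free": {"median": 33.5, "q25": 15.9, "q75": 49.5},
        "subclinical": {"median": 22.9, "q25": 10.6, "q75": 36.9},
        "severe": {"median": 19.1, "q25": 11.9, "q75": 33.8}
      }
    },
    "cimt_mm": {
      "family": "normal", "provenance": "synthetic", "truncate": [0.3, 2.0],
      "params": {
        "free": {"mean": 0.80, "sd": 0.12},
        "subclinical": {"mean": 0.95, "sd": 0.15},
        "severe": {"mean": 1.05, "sd": 0.18}
      }
    },
    "plaque_count": {
      "family": "poisson", "provenance": "synthetic",
      "params": {
        "free": {"rate": 0.8},
        "subclinical": {"rate": 2.2},
        "severe": {"rate": 3.2}
      }
    },
    "carotid_stenosis_pct": {
      "family": "normal", "provenance": "synthetic", "truncate": [0, 100],
      "params": {
        "free": {"mean": 15.0, "sd": 15.0},
        "subclinical": {"mean": 35.0, "sd": 18.0},
        "severe": {"mean": 48.0, "sd": 20.0}
      }
    }
  },
  "gs": {
    "subclinical_range": [0.5, 34.5],
    "severe": {"offset": 35.0, "median": 30.0, "q25": 15.0, "q75": 60.0}
  }
}
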