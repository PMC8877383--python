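{
  "name": "tested",
  "description": "Independent validation cohort (n=216), stratified like the initial preset. Blood-marker parameters ('reported') follow the published per-stratum summaries for this cohort; the subclinical stratum reuses the GS<35 column. One published cell (adiponectin in the GS>0 margin) prints median < Q25 and is unusable as a distribution summary; it is never needed here because strata are parameterised from the GS=0 / GS<35 / GS>=35 columns. Carotid-imaging parameters are synthetic calibration values shared with the initial preset.",
  "n_strata": {"free": 73, "subclinical": 71, "severe": 72},
  "variables": {
    "age": {
      "family": "normal", "provenance": "reported", "truncate": [18, null],
      "params": {
        "free": {"mean": 61.5, "sd": 10.7},
        "subclinical": {"mean": 61.5, "sd": 10.7},
        "severe": {"mean": 61.5, "sd": 10.7}
      }
    },
    "sex": {
      "family": "bernoulli", "provenance": "reported", "category": "male",
      "params": {
        "free": {"p": 0.532},
        "subclinical": {"p": 0.532},
        "severe": {"p": 0.532}
      }
    },
    "tc": {
      "family": "normal", "provenance": "reported", "truncate": [0, null],
      "params": {
        "free": {"mean": 4.5, "sd": 1.2},
        "subclinical": {"mean": 4.6, "sd": 1.08},
        "severe": {"mean": 3.8, "sd": 0.9}
      }
    },
    "ldl_c": {
      "family": "normal", "provenance": "reported", "truncate": [0, null],
      "params": {
        "free": {"mean": 2.6, "sd": 0.9},
        "subclinical": {"mean": 2.7, "sd": 0.9},
        "severe": {"mean": 2.2, "sd": 0.8}
      }
    },
    "hdl_c": {
      "family": "normal", "provenance": "reported", "truncate": [0, null],
      "params": {
        "free": {"mean": 1.2, "sd": 0.3},
        "subclinical": {"mean": 1.2, "sd": 0.3},
        "severe": {"mean": 1.0, "sd": 0.3}
      }
    },
    "tg": {
      "family": "lognormal", "provenance": "reported", "truncate": [0, null],
      "params": {
        "free": {"median": 1.4, "q25": 1.0, "q75": 1.9},
        "subclinical": {"median": 1.3, "q25": 0.9, "q75": 1.9},
        "severe": {"median": 1.4, "q25": 1.1, "q75": 1.8}
      }
    },
    "apo_ai": {
      "family": "normal", "provenance": "reported", "truncate": [0, null],
      "params": {
        "free": {"mean": 1.57, "sd": 0.32},
        "subclinical": {"mean": 1.58, "sd": 0.29},
        "severe": {"mean": 1.36, "sd": 0.26}
      }
    },
    "apo_b": {
      "family": "normal", "provenance": "reported", "truncate": [0, null],
      "params": {
        "free": {"mean": 0.86, "sd": 0.24},
        "subclinical": {"mean": 0.89, "sd": 0.24},
        "severe": {"mean": 0.84, "sd": 0.22}
      }
    },
    "hscrp": {
      "family": "lognormal", "provenance": "reported", "truncate": [0, null],
      "params": {
        "free": {"median": 2.3, "q25": 0.9, "q75": 5.4},
        "subclinical": {"median": 2.8, "q25": 1.1, "q75": 4.8},
        "severe": {"median": 4.5, "q25": 2.1, "q75": 10.1}
      }
    },
    "fibrinogen": {
      "family": "lognormal", "provenance": "reported", "truncate": [0, null],
      "params": {
        "free": {"median": 4.30, "q25": 3.7, "q75": 5.2},
        "subclinical": {"median": 4.30, "q25": 3.8, "q75": 5.1},
        "severe": {"median": 4.90, "q25": 4.4, "q75": 5.7}
      }
    },
    "glucose": {
      "family": "normal", "provenance": "reported", "truncate": [0, null],
      "params": {
        "free": {"mean": 5.9, "sd": 1.4},
        "subclinical": {"mean": 6.1, "sd": 1.4},
        "severe": {"mean": 6.9, "sd": 2.0}
      }
    },
    "insulin": {
      "family": "lognormal", "provenance": "reported", "truncate": [0, null],
      "params": {
        "free": {"median": 8.85, "q25": 6.1, "q75": 12.5},
        "subclinical": {"median": 9.4, "q25": 6.0, "q75": 13.8},
        "severe": {"median": 11.0, "q25": 8.2, "q75": 17.5}
      }
    },
    "adiponectin": {
      "family": "lognormal", "provenance": "reported", "truncate": [0, null],
      "params": {
        "free": {"median": 7.7, "q25": 5.9, "q75": 10.6},
        "subclinical": {"median": 8.3, "q25": 6.2, "q75": 11.4},
        "severe": {"median": 6.8, "q25": 4.7, "q75": 10.4}
      }
    },
    "leptin": {
      "family": "lognormal", "provenance": "reported", "truncate": [0, null],
      "params": {
        "free": {"median": 19.4, "q25": 5.8, "q75": 57.3},
        "subclinical": {"median": 21.4, "q25": 5.2, "q75": 70.7},
        "severe": {"median": 10.5, "q25": 4.0, "q75": 37.2}
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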