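{
  "schema_version": 1,
  "description": "Point table of the i-BIO integrated biomarker. Each banded component is encoded as ordered cut rules; a component's points are the sum of 'points' over every satisfied cut. The ultrasound composite is a 3-bit encoding of its three binary criteria (CIMT 1, plaque count 2, stenosis 4), so its value enumerates all eight combinations 0-7.",
  "components": {
    "sex": {
      "kind": "categorical",
      "input": "sex",
      "points": {"female": 0, "male": 1}
    },
    "ultrasound": {
      "kind": "cuts",
      "inputs": ["cimt_mm", "plaque_count", "carotid_stenosis_pct"],
      "cuts": [
        {"input": "cimt_mm", "op": ">", "threshold": 0.9, "points": 1},
        {"input": "plaque_count", "op": ">=", "threshold": 3, "points": 2},
        {"input": "carotid_stenosis_pct", "op": ">", "threshold": 45, "points": 4}
      ]
    },
    "tg": {
      "kind": "cuts",
      "inputs": ["tg"],
      "cuts": [
        {"input": "tg", "op": ">=", "threshold": 1.7, "points": 1},
        {"input": "tg", "op": ">=", "threshold": 2.0, "points": 1}
      ]
    },
    "glucose": {
      "kind": "cuts",
      "inputs": ["glucose"],
      "cuts": [
        {"input": "glucose", "op": ">", "threshold": 5.5, "points": 1},
        {"input": "glucose", "op": ">", "threshold": 6.0, "points": 1},
        {"input": "glucose", "op": ">=", "threshold": 7.0, "points": 1}
      ]
    },
    "fibrinogen": {
      "kind": "cuts",
      "inputs": ["fibrinogen"],
      "cuts": [
        {"input": "fibrinogen", "op": ">", "threshold": 4.0, "points": 1}
      ]
    },
    "hscrp": {
      "kind": "cuts",
      "inputs": ["hscrp"],
      "cuts": [
        {"input": "hscrp", "op": ">=", "threshold": 1.0, "points": 1},
        {"input": "hscrp", "op": ">=", "threshold": 3.0, "points": 1}
      ]
    },
    "adiponectin": {
      "kind": "cuts",
      "inputs": ["adiponectin"],
      "cuts": [
        {"input": "adiponectin", "op": "<", "threshold": 8.0, "points": 1}
      ]
    }
  },
  "thresholds": {
    "presence": {"threshold": 4, "strict": true},
    "severity": {"threshold": 9, "strict": false}
  }
}
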