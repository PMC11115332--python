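{
  "occurrence": {
    "entries": [
      {"label": "Nearly Impossible", "description": "Failure practically never occurs", "tfn": [1, 2, 3]},
      {"label": "Remote", "description": "Failure is rare and isolated", "tfn": [2, 3, 4]},
      {"label": "Very Low", "description": "Few failures observed", "tfn": [3, 4, 5]},
      {"label": "Low", "description": "Occasional failures", "tfn": [4, 5, 6]},
      {"label": "Moderate", "description": "Intermittent, repeatable failures", "tfn": [5, 6, 7]},
      {"label": "High", "description": "Frequent failures", "tfn": [6, 7, 8]},
      {"label": "Very High", "description": "Failure occurs in most exposures", "tfn": [7, 8, 9]},
      {"label": "Extremely High", "description": "Failure almost every exposure, with warning", "tfn": [8, 9, 10]},
      {"label": "Almost Certain", "description": "Failure is almost inevitable, without warning", "tfn": [9, 10, 10]}
    ]
  },
  "severity": {
    "entries": [
      {"label": "Very minor", "description": "Natural function with minor effects", "tfn": [1, 2, 3]},
      {"label": "minor", "description": "Normal performance with slight reduction", "tfn": [2, 3, 4]},
      {"label": "very Low", "description": "Normal performance with reduced", "tfn": [3, 4, 5]},
      {"label": "Low", "description": "Abnormal performance with little", "tfn": [4, 5, 6]},
      {"label": "Moderate", "description": "Abnormal and repairable performance", "tfn": [5, 6, 7]},
      {"label": "high", "description": "Abnormal performance", "tfn": [6, 7, 8]},
      {"label": "very high", "description": "Destructive changes", "tfn": [7, 8, 9]},
      {"label": "Dangerous with warnings", "description": "Extremely high event intensity with alert", "tfn": [8, 9, 10]},
      {"label": "Dangerous without warning", "description": "Extreme intensity without warning", "tfn": [9, 10, 10]}
    ]
  },
  "detection": {
    "entries": [
      {"label": "Very High", "description": "Chance of discovery is very high", "tfn": [1, 1, 3]},
      {"label": "High", "description": "High chance of discovery", "tfn": [1, 3, 5]},
      {"label": "Moderate", "description": "Probability so-so", "tfn": [3, 5, 7]},
      {"label": "Low", "description": "Low chance by experiment", "tfn": [5, 7, 9]},
      {"label": "Remote", "description": "No chance to discover", "tfn": [8, 10, 10]}
    ],
    "aliases": {"M": "Moderate", "Very Low": "Low"}
  },
  "rpn_output": {
    "entries": [
      {"label": "VL", "description": "Very Low", "tfn": [0, 0, 0.25]},
      {"label": "L", "description": "Low", "tfn": [0, 0.25, 0.5]},
      {"label": "M", "description": "Moderate", "tfn": [0.25, 0.5, 0.75]},
      {"label": "H", "description": "High", "tfn": [0.5, 0.75, 1]},
      {"label": "VH", "description": "Very High", "tfn": [0.75, 1, 1]}
    ],
    "aliases": {
      "Very Low": "VL", "Low": "L", "Moderate": "M", "High": "H", "Very High": "VH"
    }
  }
}
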