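[
  {
    "reference_id": "synthetic-aao-ga-linear",
    "structure": "aao",
    "predictor": "ga_weeks",
    "transform": "identity",
    "range": [14, 42],
    "mean": [0.25, 0.16],
    "sd": [0.08, 0.015]
  },
  {
    "reference_id": "synthetic-isthmus3vt-ga-linear",
    "structure": "isthmus_3vt",
    "predictor": "ga_weeks",
    "transform": "identity",
    "range": [14, 42],
    "mean": [0.2, 0.11],
    "sd": [0.05, 0.013]
  },
  {
    "reference_id": "synthetic-isthmus-sagittal-ga-linear",
    "structure": "isthmus_sagittal",
    "predictor": "ga_weeks",
    "transform": "identity",
    "range": [14, 42],
    "mean": [0.25, 0.105],
    "sd": [0.05, 0.012]
  },
  {
    "reference_id": "synthetic-av-ga-linear",
    "structure": "av",
    "predictor": "ga_weeks",
    "transform": "identity",
    "range": [14, 42],
    "mean": [0.34, 0.145],
    "sd": [0.45]
  },
  {
    "reference_id": "synthetic-pv-ga-linear",
    "structure": "pv",
    "predictor": "ga_weeks",
    "transform": "identity",
    "range": [14, 42],
    "mean": [0.3, 0.18],
    "sd": [0.5]
  },
  {
    "reference_id": "synthetic-mv-ga-linear",
    "structure": "mv",
    "predictor": "ga_weeks",
    "transform": "identity",
    "range": [14, 42],
    "mean": [0.4, 0.32],
    "sd": [1.0]
  },
  {
    "reference_id": "synthetic-tv-ga-linear",
    "structure": "tv",
    "predictor": "ga_weeks",
    "transform": "identity",
    "range": [14, 42],
    "mean": [0.5, 0.36],
    "sd": [1.1]
  },
  {
    "reference_id": "synthetic-mpa-ga-linear",
    "structure": "mpa",
    "predictor": "ga_weeks",
    "transform": "identity",
    "range": [14, 42],
    "mean": [0.3, 0.2],
    "sd": [0.6]
  },
  {
    "reference_id": "synthetic-da-ga-linear",
    "structure": "da",
    "predictor": "ga_weeks",
    "transform": "identity",
    "range": [14, 42],
    "mean": [0.2, 0.1],
    "sd": [0.4]
  }
]
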