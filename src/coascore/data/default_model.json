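{
  "parameters": [
    {
      "id": "ga_weeks",
      "cutoff": 28,
      "direction": "le",
      "lr_pos": 4.3,
      "lr_neg": 0.3,
      "lr_pos_ci": [2.0, 8.8],
      "lr_neg_ci": [0.1, 0.5]
    },
    {
      "id": "aao_zscore",
      "cutoff": -1.5,
      "direction": "le",
      "lr_pos": 2.8,
      "lr_neg": 0.4,
      "lr_pos_ci": [1.4, 5.6],
      "lr_neg_ci": [0.2, 0.7]
    },
    {
      "id": "isthmus_3vt_zscore",
      "cutoff": -2,
      "direction": "le",
      "lr_pos": 1.8,
      "lr_neg": 0.6,
      "lr_pos_ci": [0.8, 3.8],
      "lr_neg_ci": [0.3, 1.2]
    },
    {
      "id": "pv_av_ratio",
      "cutoff": 1.6,
      "direction": "ge",
      "lr_pos": 1.8,
      "lr_neg": 0.4,
      "lr_pos_ci": [1.1, 3.1],
      "lr_neg_ci": [0.2, 0.9]
    }
  ],
  "pretest": {
    "coao": 41,
    "no_coao": 44
  }
}
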