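{
  "weights": [
    -1.2901908427847104,
    13.062413151918003,
    22.106129853030335,
    3.506756702124451e-09
  ],
  "bias": -34.204987728528685,
  "provenance": "calibrate_classifier(seed=20260922, n_pos=269, n_neg=538)",
  "report": {
    "n_pos": 269,
    "n_neg": 538,
    "train_error": 0.11028500619578686,
    "false_positive_rate": 0.06319702602230483,
    "false_negative_rate": 0.20446096654275092,
    "median_p_pos": 0.7942297968809096,
    "median_p_neg": 0.06837703175564089
  }
}
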