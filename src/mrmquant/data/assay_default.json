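{
  "analytes": [
    {
      "name": "ATV",
      "calibration_levels": [0.5, 1.0, 1.5, 3.0, 10.0, 25.0, 50.0, 80.0, 100.0, 125.0],
      "qc_low": 1.5,
      "qc_mid": 45.0,
      "qc_high": 95.0,
      "model_order": "linear",
      "weighting": "1/x",
      "is_name": "ATV-d5",
      "retention_time_min": 3.57,
      "mrm_transition": "559.3>440.3"
    },
    {
      "name": "2-OH ATV",
      "calibration_levels": [0.5, 1.0, 1.5, 3.0, 10.0, 25.0, 50.0, 80.0, 100.0, 125.0],
      "qc_low": 1.5,
      "qc_mid": 45.0,
      "qc_high": 95.0,
      "model_order": "linear",
      "weighting": "1/x",
      "is_name": "2-OH ATV-d5",
      "retention_time_min": 3.48,
      "mrm_transition": "575.3>250.2"
    },
    {
      "name": "ATV L",
      "calibration_levels": [1.2, 2.4, 8.0, 20.0, 40.0, 64.0, 80.0, 100.0],
      "qc_low": 3.6,
      "qc_mid": 36.0,
      "qc_high": 76.0,
      "model_order": "linear",
      "weighting": "1/x^2",
      "is_name": "ATV-d5 L",
      "retention_time_min": 3.77,
      "mrm_transition": "541.3>276.2"
    },
    {
      "name": "2-OH ATV L",
      "calibration_levels": [0.5, 1.0, 1.5, 3.0, 10.0, 25.0, 50.0, 80.0, 100.0, 125.0],
      "qc_low": 1.5,
      "qc_mid": 45.0,
      "qc_high": 95.0,
      "model_order": "linear",
      "weighting": "1/x^2",
      "is_name": "2-OH ATV-d5 L",
      "retention_time_min": 3.66,
      "mrm_transition": "557.3>276.2"
    },
    {
      "name": "BSP",
      "calibration_levels": [0.5, 1.0, 1.5, 3.0, 10.0, 25.0, 50.0, 80.0, 100.0, 125.0],
      "qc_low": 1.5,
      "qc_mid": 45.0,
      "qc_high": 95.0,
      "model_order": "linear",
      "weighting": "1/x^2",
      "is_name": "BSP-d5",
      "retention_time_min": 2.33,
      "mrm_transition": "326.2>116.2"
    },
    {
      "name": "CLP-CA",
      "calibration_levels": [15.0, 30.0, 45.0, 90.0, 300.0, 750.0, 1500.0, 2400.0, 3000.0, 3750.0],
      "qc_low": 45.0,
      "qc_mid": 1350.0,
      "qc_high": 2850.0,
      "model_order": "quadratic",
      "weighting": "1/x",
      "is_name": "CLP-d4 CA",
      "retention_time_min": 2.14,
      "mrm_transition": "308.0>198.1"
    }
  ]
}
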