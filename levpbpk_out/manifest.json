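{
  "config": {
    "compound": "levetiracetam",
    "subject": {
      "type": "adult",
      "weight_kg": 70.0,
      "height_m": 1.7,
      "age_years": 30.0,
      "sex": "M",
      "bmi": null
    },
    "population": {
      "n": 24,
      "age_range_years": [
        25.0,
        50.0
      ],
      "sex_ratio_male": 0.5,
      "weight_range_kg": [
        54.33,
        67.91
      ],
      "bmi_range": [
        21.3,
        23.88
      ]
    },
    "regimen": {
      "route": "oral",
      "dose_mg": null,
      "infusion_h": 0.0,
      "loading_mg": 0.0,
      "maintenance_mg": null,
      "interval_h": 12.0,
      "duration_days": 7.0,
      "miss_at_h": [],
      "remediate_time_h": null,
      "remediate_dose_mg": null,
      "candidates_mg": []
    },
    "dissolution": {
      "test": "lev_idt_1000",
      "reference": "spritam_1000"
    },
    "simulation": {
      "t_end_h": 36.0,
      "vbe_dose_mg": 1000.0,
      "be_limits_percent": [
        85.0,
        120.0
      ],
      "window_ug_ml": [
        5.0,
        19.0
      ]
    },
    "output_dir": "levpbpk_out",
    "seed": 0
  },
  "config_sha256": "a793bd3cc65f50686da80a266a4c7717ab17f79ee25b9c28c942290999d33d4d",
  "seed": 0,
  "versions": {
    "levpbpk": "0.1.0",
    "numpy": "2.4.6",
    "pandas": "2.3.3"
  },
  "timestamp": "2026-09-26T23:25:31",
  "gate_passed": true
}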