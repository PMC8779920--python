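# 6-year-old (22.26 kg, BMI 16.07) on 280 mg loading + 222.6 mg q12h for a
# week; ranks remedial doses for a dose missed at 60 h, remediated at 72 h.
#   levpbpk dose-design -c src/levpbpk/data/examples/child-6y-remediation.yaml
compound: levetiracetam
subject:
  type: child
  age_years: 6
  weight_kg: 22.26
  bmi: 16.07
regimen:
  loading_mg: 280
  maintenance_mg: 222.6
  interval_h: 12
  duration_days: 7
  miss_at_h: [60]
  remediate_time_h: 72
  candidates_mg: [275, 300, 350]
output_dir: levpbpk_out/child-6y
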