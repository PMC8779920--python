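# Adult IV validation regimen: 1500 mg infused over 45 min into the
# 64.19-kg cohort subject. Run with:
#   levpbpk simulate -c src/levpbpk/data/examples/adult-iv-1500.yaml
compound: levetiracetam
subject:
  type: adult
  weight_kg: 64.19
  height_m: 1.70
  age_years: 23.7
  sex: M
regimen:
  route: iv_infusion
  dose_mg: 1500
  infusion_h: 0.75
simulation:
  t_end_h: 36
output_dir: levpbpk_out/adult-iv-1500
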