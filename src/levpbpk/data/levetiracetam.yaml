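# Default compound profile: levetiracetam (LEV), BCS class I.
# permeability_log_scale maps the in vitro (Caco-2-type) permeability onto
# the human effective-permeability scale; it was calibrated once so that the
# adult 1500-mg oral simulation absorbs 96.7% of the dose, and is not refit
# per run.
# aqueous_solubility: the literature prints the solubility with a
# dimensionally impossible unit; the value here is the freely-soluble
# 104 mg/mL figure (dissolution is never solubility-limited for LEV).
compound:
  name: levetiracetam
  molecular_weight: 170.21        # g/mol
  log_p: 0.8
  pka: 16.1                       # effectively un-ionized at all gut/plasma pH
  log_d: 0.9
  blood_plasma_ratio: 1.11
  fraction_unbound_plasma: 0.97
  aqueous_solubility_mg_ml: 104.0
  effective_permeability_cm_s: 9.6e-6
  permeability_log_scale: 2.0207  # calibrated: Fa(1500 mg, adult) = 0.967
  clearance_plasma_l_h_kg: 0.063            # adult, derived from IV data
  clearance_plasma_child_l_h_kg: 0.053      # Chinese children (0.88 mL/min/kg)
  clearance_plasma_literature_l_h_kg: 0.0576  # adult literature 0.96 mL/min/kg
  renal_fraction: 0.66
  vd_reference_range_l_kg: [0.5, 0.7]
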