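# Dosing regimens and cohort anthropometrics for the adult validation set.
# The IV dose was given as a 45-min infusion (observed Tmax 0.711 h).
# height is a representative cohort value (only weights were reported).
regimen,route,dose_mg,infusion_h,weight_kg,height_m,age_years,sex
iv-1500,iv_infusion,1500,0.75,64.19,1.70,23.7,M
oral-250,oral,250,0,58.8,1.65,21.0,M
oral-500,oral,500,0,58.8,1.65,21.0,M
oral-750,oral,750,0,58.8,1.65,21.0,M
oral-1000,oral,1000,0,57.4,1.65,33.8,M
oral-1500,oral,1500,0,64.19,1.70,23.7,M
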