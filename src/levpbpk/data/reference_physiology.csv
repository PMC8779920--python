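# 70-kg reference adult male. volume_frac_bw: tissue volume as fraction of
# body weight (density ~1 kg/L); flow_frac_co: tissue blood flow as fraction
# of cardiac output. Gut and spleen drain through the portal vein to the
# liver, whose flow_frac_co entry is the hepatic-artery share only.
tissue,volume_frac_bw,flow_frac_co
adipose,0.2142,0.050
bone,0.0856,0.050
brain,0.0200,0.120
gut,0.0171,0.150
heart,0.0047,0.040
kidney,0.0044,0.190
liver,0.0257,0.065
lung,0.0076,1.000
muscle,0.4000,0.170
skin,0.0371,0.050
spleen,0.0026,0.020
rest,0.0400,0.095
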