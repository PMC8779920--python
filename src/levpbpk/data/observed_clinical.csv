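# Observed adult clinical PK parameters by regimen (literature cohorts).
# Units: cmax ug/mL, auc0t and auc0inf ug.h/mL, tmax h.
regimen,parameter,observed
iv-1500,cmax,50.80
iv-1500,auc0t,367.20
iv-1500,auc0inf,370.70
iv-1500,tmax,0.711
oral-250,cmax,5.51
oral-250,auc0t,62.56
oral-250,auc0inf,72.56
oral-250,tmax,1.67
oral-500,cmax,12.50
oral-500,auc0t,138.50
oral-500,auc0inf,145.40
oral-500,tmax,0.80
oral-750,cmax,17.00
oral-750,auc0t,189.80
oral-750,auc0inf,196.10
oral-750,tmax,3.16
oral-1000,cmax,24.10
oral-1000,auc0t,222.80
oral-1000,auc0inf,226.40
oral-1000,tmax,1.45
oral-1500,cmax,35.30
oral-1500,auc0t,402.30
oral-1500,auc0inf,408.30
oral-1500,tmax,0.646
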