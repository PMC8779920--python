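regimen,parameter,observed,predicted,pe_percent
iv-1500,cmax,50.8,43.504157699823246,14.36189429168652
iv-1500,auc0t,367.2,358.6638694843084,2.3246542798724352
iv-1500,auc0inf,370.7,370.90216020664127,0.05453471989244162
iv-1500,tmax,0.711,0.75,5.4852320675105535
oral-250,cmax,5.51,5.497787225456748,0.2216474508757105
oral-250,auc0t,62.56,62.27998674760735,0.44759151597290486
oral-250,auc0inf,72.56,64.47834694646033,11.13789009583747
oral-250,tmax,1.67,1.0,40.119760479041915
oral-500,cmax,12.5,10.995561225513226,12.03551019589419
oral-500,auc0t,138.5,124.55990226203278,10.065052518387885
oral-500,auc0inf,145.4,128.95662499494006,11.309061213933939
oral-500,tmax,0.8,1.0,24.999999999999993
oral-750,cmax,17.0,16.49332143823069,2.9804621280547603
oral-750,auc0t,189.8,186.83974343651684,1.55967152975931
oral-750,auc0inf,196.1,193.43483114282233,1.359086617632668
oral-750,tmax,3.16,1.0,68.35443037974683
oral-1000,cmax,24.1,22.551398305931137,6.425733170410225
oral-1000,auc0t,222.8,255.37327742973088,14.619962939735576
oral-1000,auc0inf,226.4,264.38112726063275,16.77611628119821
oral-1000,tmax,1.45,1.0,31.034482758620687
oral-1500,cmax,35.3,30.096777482021384,14.74000713308389
oral-1500,auc0t,402.3,341.4059296739407,15.136482805383869
oral-1500,auc0inf,408.3,353.4883323012029,13.424361425127875
oral-1500,tmax,0.646,1.0,54.79876160990712
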