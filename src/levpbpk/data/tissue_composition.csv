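# Fractional tissue composition (volume fractions) for the
# tissue-composition Kp equations: water, neutral lipid, phospholipid.
# Standard adult human values; the "rest" row is a low-water catch-all for
# connective tissue and other unassigned mass.
tissue,f_water,f_neutral_lipid,f_phospholipid
adipose,0.180,0.7900,0.00200
bone,0.439,0.0740,0.00110
brain,0.770,0.0510,0.05650
gut,0.718,0.0487,0.01630
heart,0.758,0.0115,0.01660
kidney,0.783,0.0207,0.01620
liver,0.751,0.0348,0.02520
lung,0.811,0.0030,0.00900
muscle,0.760,0.0238,0.00720
skin,0.718,0.0284,0.01110
spleen,0.788,0.0201,0.01980
rest,0.450,0.0200,0.00500
plasma,0.960,0.0023,0.00130
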