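# In vitro release of the reference instant-dissolving product (1000 mg
# strength) in pH 1.2 medium, USP II paddle, 50 rpm.
time_min,percent_dissolved
2.5,89.0
5,100.0
10,100.0
15,100.0
20,100.0
30,100.0
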