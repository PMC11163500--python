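field_mm,p_housing,p_sens,p_vol,k_total,p_housing_alt,source_quote
3,0.9725,0.989,1.075,1.033,0.973,"reported 3 mm factors: housing over-response (discussion value; results section prints 0.973), sensitive-volume material, volume averaging, and the printed total"
4,0.980,,1.022,0.998,,"reported 4 mm housing and volume-averaging factors with the printed total"
5,,,,0.988,,"printed 5 mm total correction factor only"
25,1.0,1.0,1.0,1.0,1.0,"machine-specific reference (msr) field: all factors unity by normalization"
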