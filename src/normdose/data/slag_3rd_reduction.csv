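nuclide,activity_Bq_per_kg,uncertainty_pct
U-238,120,17
U-234,127,18
Th-230,1363,22
Ra-226,5098,13
Pb-210,2415,21
Po-210,2293,17
U-235,6,45
Pa-231,48,36
Ac-227,104,33
Th-232,123,27
Ra-228,127,24
Th-228,131,27
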