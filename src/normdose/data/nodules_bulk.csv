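nuclide,activity_Bq_per_kg,uncertainty_pct
U-238,55,17
U-234,58,18
Th-230,620,22
Ra-226,2317,13
Pb-210,1098,21
Po-210,1042,17
U-235,3,45
Pa-231,22,36
Ac-227,47,33
Th-232,56,27
Ra-228,58,24
Th-228,60,27
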