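nuclide,g_inh_uSv_per_Bq,absorption_class
U-238,1.6,M
U-234,2.1,M
Th-230,28,S
Ra-226,2.2,M
Pb-210,1.1,M
Po-210,2.2,M
U-235,1.8,M
Pa-231,89,M
Ac-227,630,F
Th-232,12,S
Ra-228,1.7,M
Th-228,22,S
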