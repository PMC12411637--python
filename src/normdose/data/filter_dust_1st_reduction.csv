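nuclide,activity_Bq_per_kg,uncertainty_pct
Pb-210,10975,21
Po-210,10422,17
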