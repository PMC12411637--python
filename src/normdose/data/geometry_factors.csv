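label,adr_surface_uSv_h_per_Bq_g,adr_1m_uSv_h_per_Bq_g
extended_surface,0.5,0.5
cone_pile,0.4,0.2
big_bag,0.3,0.07
two_big_bags,0.3,0.15
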