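# Bulk-carrier transport of nodules: a reference person operating in the
# engine room next to a full cargo hold for a whole working year.  Dust and
# radon inhalation are excluded (no air exchange with the hold); 2 cm of
# steel sheets plus installations transmit ~50% of the gamma dose rate.
label = "transport"

[[gamma]]
label = "nodules in cargo hold"
material = "nodules_bulk"
geometry = "extended_surface"   # lateral infinitely extended surface (2pi)
distance = "surface"
t_exp_h = 2000
shielding = 0.5                 # transmitted fraction behind the steel wall
f_con = 0.6
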