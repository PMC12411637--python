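# Pyrometallurgical processing plant: one reference person covers all
# workplaces pro rata.  400 h/a next to each outdoor storage area (nodules
# and third-stage slag), 1000 h/a indoors exposed to both nodule and slag
# dust at the routine A-dust limit, and 2 h/month of filter maintenance at
# the occasional-exposure limit.  No masks, no dust suppression, no gamma
# shielding by vehicle cabins — deliberately conservative.  The radon block
# uses the 300 Bq/m3 workplace reference concentration and is reported
# separately from the gamma+dust subtotal.
label = "processing_plant"

[[gamma]]
label = "stored nodules"
material = "nodules_bulk"
geometry = "cone_pile"          # large stockpiles: 0.4 uSv/h per Bq/g
distance = "surface"
t_exp_h = 400

[[gamma]]
label = "stored slag"
material = "slag_3rd_reduction"
geometry = "big_bag"            # <= 1 m3 handling units, at 1 m: 0.07
distance = "1m"
t_exp_h = 400

[[dust]]
label = "nodule dust"
material = "nodules_bulk"
c_dust_mg_m3 = 1.25
t_exp_h = 1000

[[dust]]
label = "slag dust"
material = "slag_3rd_reduction"
c_dust_mg_m3 = 1.25
t_exp_h = 1000

[[dust]]
label = "filter maintenance"
material = "filter_dust_1st_reduction"
c_dust_mg_m3 = 3.0
t_exp_h = 24

[radon]
concentration_bq_m3 = 300
t_exp_h = 2000
equilibrium_factor = 0.4
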