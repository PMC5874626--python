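quantity,value
flux_mmol_m2_d,1.19332
din_flux_mmol_m2_d,6.5
din_nh4_share,0.969231
jar_slope_uM_d,7.14286
jar_rate_nmol_cm3_d,3.57143
areal_production_mmol_m2_d,0.525
porewater_inventory_mmol_m2,100
potential_denitrification_mmol_m2_d,6
potential_nh4_oxidation_mmol_m2_d,7
denitrified_fraction,0.6
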