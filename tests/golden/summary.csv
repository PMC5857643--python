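quantity,value
total_excess_n_t,871.821
total_excess_p_t,114.542
n_cells,100
n_cells_with_data,96
n_cells_n_limited,60
n_cells_p_limited,36
total_biomass_t_yr,16817.5732
total_ats_area_ha,188.6498754
half_mass_cell_fraction_n,0.09375
bin_top10_n_t,114.994
bin_next40_n_t,336.465
bin_bottom50_n_t,420.362
half_mass_cell_fraction_p,0.1
bin_top10_p_t,14.774
bin_next40_p_t,44.718
bin_bottom50_p_t,55.05
r_pn,0.1382076819
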