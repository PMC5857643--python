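rank,basin,name,ats_area_ha,share_pct,cum_share_pct,pct_of_basin_area
1,east,East fixture basin,103.4417001,54.83263631,54.83263631,0.0001675355839
2,west,West fixture basin,85.20817533,45.16736369,100,0.0001380043193
,unbasined,unbasined,0,,,
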