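{
 "model_id": "3",
 "V_syn": 380,
 "C_sol_cyt": 2157,
 "C_cyt_ims": 606,
 "C_c4": 0.872,
 "V_atpase1": 102,
 "Km_atp1": 0.068,
 "Km_adp1": 0.05,
 "V_atpase2": 183,
 "Km_atp2": 9.46,
 "Km_adp2": 0.051,
 "V_pkend1": 395,
 "Km_pk_adp": 0.533,
 "V_pkend2": 6925
}
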