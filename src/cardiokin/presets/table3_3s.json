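{
 "model_id": "3s",
 "V_syn": 380,
 "C_sol_cyt": 2011,
 "C_cyt_ims": 610,
 "C_c4": 7.59,
 "V_atpase1": 81,
 "Km_atp1": 0.058,
 "Km_adp1": 0.085,
 "V_atpase2": 4410,
 "V_pkend1": 421,
 "Km_pk_adp": 0.64,
 "V_pkend2": 44
}
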