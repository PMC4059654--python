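{
 "model_id": "4s",
 "V_syn": 380,
 "C_sol_cyt": 1992,
 "C_cyt_ims": 611,
 "C_c4": 7.4,
 "V_atpase1": 80,
 "Km_atp1": 0.057,
 "Km_adp1": 0.079,
 "V_atpase2": 4500,
 "V_pkend1": 420,
 "Km_pk_adp": 0.641,
 "V_pkend2": 46
}
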