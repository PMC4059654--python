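{
 "model_id": "2",
 "V_syn": 380,
 "C_sol_cyt": 3151,
 "C_cyt_ims": 559,
 "V_atpase1": 367,
 "Km_atp1": 10.0,
 "Km_adp1": 0.05,
 "V_atpase2": 87,
 "Km_atp2": 0.051,
 "Km_adp2": 0.05,
 "V_pkend1": 461,
 "Km_pk_adp": 0.625
}
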