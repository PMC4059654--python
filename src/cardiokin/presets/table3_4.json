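{
 "model_id": "4",
 "V_syn": 384,
 "C_sol_cyt": 1412,
 "C_cyt_ims": 612,
 "C_c4": 527,
 "V_atpase1": 372,
 "Km_atp1": 9.99,
 "Km_adp1": 0.05,
 "V_atpase2": 88,
 "Km_atp2": 0.051,
 "Km_adp2": 0.051,
 "V_pkend1": 0.329,
 "Km_pk_adp": 0.164,
 "V_pkend2": 410
}
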