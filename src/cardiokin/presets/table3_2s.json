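{
 "model_id": "2s",
 "V_syn": 380,
 "C_sol_cyt": 2727,
 "C_cyt_ims": 574,
 "V_atpase1": 116,
 "Km_atp1": 0.087,
 "Km_adp1": 0.05,
 "V_pkend1": 460,
 "Km_pk_adp": 0.614
}
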