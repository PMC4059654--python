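{
 "model_id": "1",
 "V_syn": 380,
 "C_sol_cyt": 3126,
 "C_cyt_ims": 558,
 "V_atpase1": 95,
 "Km_atp1": 0.053,
 "Km_adp1": 0.05
}
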