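{
 "alpha1": 9.0,
 "alpha2": 17.5,
 "alpha3": 2.5,
 "alpha4": 3.5,
 "alpha4_exp": 3.0,
 "alpha5": 0.65,
 "alpha6": 10.0,
 "alpha7": 1.0,
 "alpha8": 4.8,
 "base_cebpa": 0.1,
 "base_cebpb": 0.012,
 "base_ir": 0.1,
 "base_pparg": 0.05,
 "deg_cebpa": 0.2,
 "deg_cebpb": 0.2,
 "deg_fat": 0.06,
 "deg_ir": 0.05,
 "deg_pakt": 1.0,
 "deg_pparg": 0.2,
 "rosi_gain": 24.0,
 "rosi_k": 1.0,
 "syn_cebpa": 1.6287703016,
 "syn_cebpb": 8.2661290323,
 "syn_fat": 0.696,
 "syn_ir": 0.2619047619,
 "syn_pakt": 0.9090909091,
 "syn_pparg": 4.0
}
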