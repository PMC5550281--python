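dan,compartment,n_post_kc,total_synapses,mean_per_kc
PPL1-a3-A,a3,706,1336,1.89
PPL1-a3-B,a3,786,1646,2.09
PPL1-ap2a2-A,a2,455,653,1.44
PPL1-ap2a2-B,a2,484,813,1.68
PAM-a1-A,a1,158,182,1.15
PAM-a1-B,a1,121,134,1.11
PAM-a1-C,a1,149,181,1.21
PAM-a1-D,a1,149,170,1.14
PAM-a1-E,a1,163,177,1.09
PAM-a1-F,a1,135,151,1.12
PAM-a1-G,a1,123,138,1.12
PAM-a1-H,a1,95,105,1.11
PAM-a1-I,a1,71,81,1.14
PAM-a1-J,a1,100,112,1.12
PAM-a1-K,a1,40,43,1.07
PAM-a1-L,a1,89,95,1.07
PAM-a1-M,a1,148,179,1.21
PAM-a1-N,a1,78,125,1.60
PAM-a1-O,a1,52,56,1.08
PAM-a1-P,a1,61,82,1.34
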