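dan,compartment,n_pre_kc,total_synapses,mean_per_kc
PPL1-a3-A,a3,883,2822,3.20
PPL1-a3-B,a3,834,2215,2.66
PPL1-ap2a2-A,a2,488,809,1.66
PPL1-ap2a2-B,a2,480,791,1.65
PAM-a1-A,a1,209,251,1.20
PAM-a1-B,a1,239,332,1.39
PAM-a1-C,a1,218,283,1.30
PAM-a1-D,a1,191,256,1.34
PAM-a1-E,a1,194,254,1.31
PAM-a1-F,a1,193,241,1.25
PAM-a1-G,a1,143,171,1.20
PAM-a1-H,a1,156,176,1.13
PAM-a1-I,a1,156,212,1.36
PAM-a1-J,a1,124,149,1.20
PAM-a1-K,a1,86,97,1.13
PAM-a1-L,a1,174,215,1.24
PAM-a1-M,a1,218,266,1.22
PAM-a1-N,a1,49,59,1.20
PAM-a1-O,a1,50,56,1.12
PAM-a1-P,a1,29,36,1.24
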