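dan_type,mbon,total_synapses,printed_percent
PPL1-a3,MBON-a3-A,456,3.57
PPL1-a3,MBON-a3-B,451,3.43
PPL1-ap2a2,MBON-a2p3p-A,26,1.95
PPL1-ap2a2,MBON-a2p3p-B,12,1.66
PPL1-ap2a2,MBON-a2sc,246,2.18
PPL1-ap2a2,MBON-a2sp,91,2.57
PAM-a1,MBON-a1-A,727,7.77
PAM-a1,MBON-a1-B,736,7.90
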