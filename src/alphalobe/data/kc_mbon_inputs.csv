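mbon,n_connected_kc,total_synapses,mean_per_connected_kc,n_sc,pct_sc,n_p,pct_p
MBON-a3-A,948,12770,13.47,12278,96.1,492,3.9
MBON-a3-B,948,13129,13.85,12425,94.6,704,5.4
MBON-a2p3p-A,236,1311,5.56,325,24.8,986,75.2
MBON-a2p3p-B,168,692,4.12,113,16.3,579,83.7
MBON-a2sc,909,11281,12.41,11214,99.4,67,0.6
MBON-a2sp,823,3529,4.29,2835,80.3,694,19.7
MBON-a1-A,949,9303,9.80,8239,88.6,1064,11.4
MBON-a1-B,949,9286,9.79,8178,88.1,1108,11.9
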