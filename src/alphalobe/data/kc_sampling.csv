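mbon,kc_subtype,n_connected,n_available,mean_among_connected
MBON-a3-A,KC-ab-s,480,480,15.88
MBON-a3-A,KC-ab-c-o,131,132,13.27
MBON-a3-A,KC-ab-c-i,259,259,11.26
MBON-a3-A,KC-ab-p,78,78,6.31
MBON-a3-B,KC-ab-s,480,480,16.32
MBON-a3-B,KC-ab-c-o,131,132,12.60
MBON-a3-B,KC-ab-c-i,259,259,11.36
MBON-a3-B,KC-ab-p,78,78,9.03
MBON-a2p3p-A,KC-ab-s,138,480,2.17
MBON-a2p3p-A,KC-ab-c-o,15,132,1.27
MBON-a2p3p-A,KC-ab-c-i,5,259,1.20
MBON-a2p3p-A,KC-ab-p,78,78,12.64
MBON-a2p3p-B,KC-ab-s,80,480,1.27
MBON-a2p3p-B,KC-ab-c-o,9,132,1.11
MBON-a2p3p-B,KC-ab-c-i,1,259,1.00
MBON-a2p3p-B,KC-ab-p,78,78,7.42
MBON-a2sc,KC-ab-s,480,480,14.13
MBON-a2sc,KC-ab-c-o,132,132,13.67
MBON-a2sc,KC-ab-c-i,259,259,10.14
MBON-a2sc,KC-ab-p,38,78,1.76
MBON-a2sp,KC-ab-s,470,480,4.33
MBON-a2sp,KC-ab-c-o,130,132,3.58
MBON-a2sp,KC-ab-c-i,145,259,2.30
MBON-a2sp,KC-ab-p,78,78,8.90
MBON-a1-A,KC-ab-s,480,480,10.73
MBON-a1-A,KC-ab-c-o,132,132,7.99
MBON-a1-A,KC-ab-c-i,259,259,7.85
MBON-a1-A,KC-ab-p,78,78,13.64
MBON-a1-B,KC-ab-s,480,480,10.86
MBON-a1-B,KC-ab-c-o,132,132,8.57
MBON-a1-B,KC-ab-c-i,259,259,7.09
MBON-a1-B,KC-ab-p,78,78,14.21
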