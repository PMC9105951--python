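decile,births_thousands,mean_hb_gdl,income_share_pct,hb_sd_gdl,tertile
1,436,10.4,1.92,1.4,1
2,427,10.4,3.21,1.4,1
3,418,10.5,4.23,1.4,1
4,413,10.6,5.18,1.4,2
5,400,10.8,6.28,1.4,2
6,376,10.9,7.6,1.4,2
7,371,11.1,9.29,1.4,2
8,370,11.1,11.6,1.4,3
9,357,11.2,15.9,1.4,3
10,355,11.2,34.8,1.4,3
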