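pair,cor,pis,ms_e4,time_years,label_pis,label_ms,label_clinical,divergence
1,1,0.019,4.42,6.5,NP,NP,NP,
2,3,0.435,7.82,3.2,TR,TR,TR,
3,11,0.018,3.95,6.4,NP,NP,NP,
4,16,0.303,5.59,3.8,TR,NP,NP,PIS
5,12,0.113,6.11,3.4,NP,NP,NP,
6,13,0.214,9.29,4.6,TR,TR,TR,
7,15,0.105,5.36,3.2,NP,NP,TR,Clinical
8,2,0,7.57,5.2,NP,TR,NP,MS
9,4,0.203,9.76,3.5,TR,TR,TR,
10,14,0.321,6.64,2.4,TR,TR,TR,
11,18,0.003,5.44,2.2,NP,NP,NP,
12,20,0.103,5.60,1.4,NP,NP,NP,
13,21,0.356,6.82,4.2,TR,TR,TR,
14,23,0.328,5.37,0.9,TR,NP,TR,MS
15,24,0.312,6.69,1.4,TR,TR,TR,
16,25,0.357,9.09,2.7,TR,TR,TR,
17,26,0.493,8.69,2.0,TR,TR,TR,
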