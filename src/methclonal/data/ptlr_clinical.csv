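pair,cor,age,pt_type,pt_grade,pt_er,pt_pr,pt_her2,lr_type,lr_grade,lr_er,lr_pr,lr_her2,loc,discordance
1,1,23.3,D,3,-,+,-,D,2,+,+,-,1,ER
2,3,42.9,D,3,+,+,-,D,3,+,+,-,1,
3,11,49.3,L,3,-,-,-,D,3,-,-,+,1,HER2
4,16,48.8,D,2,+,+,-,D,1,+,+,-,1,
5,12,49.3,L,2,+,+,-,L,2,+,-,-,0,PR
6,13,45.4,D,2,+,+,-,D,2,+,+,-,1,
7,15,46.5,D,2,+,+,-,D,2,+,+,-,1,
8,2,42.4,D,2,+,+,-,L,1,+,+,,1,
9,4,48.6,L,1,+,+,-,L,2,+,+,-,1,
10,14,44,L,2,+,+,-,L,2,-,+,-,1,ER
11,18,,D,3,-,-,,D,2,+,+,,1,ER/PR
12,20,47.5,D,3,-,-,+,D,3,-,-,+,0,
13,21,46.7,D,2,+,-,,D,3,+,-,-,1,
14,23,31,D,2,-,-,-,D,3,-,-,-,1,
15,24,48.1,D,3,-,-,-,D,3,-,-,-,1,
16,25,43.3,D,3,+,+,-,D,3,+,+,-,1,
17,26,30.8,D,3,-,-,-,D,3,-,-,-,1,
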