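pair,age,pt_type,pt_grade,pt_er,pt_pr,pt_her2,cl_type,cl_grade,cl_er,cl_pr,cl_her2,discordance
1,46.6,L,3,+,+,-,,,+,+,-,
2,46.9,D,2,+,+,-,D,2,+,+,-,
3,48.4,D,3,+,+,-,D,3,+,+,-,
4,42.6,D,2,-,-,-,D-L,2,+,+,-,ER/PR
5,48.5,D,2,+,+,-,D,3,+,+,-,
6,44.5,D,2,+,+,-,Med,2,-,-,-,ER/PR
7,46,D,2,+,+,-,D,1,+,+,-,
8,48.9,D,3,+,+,-,Meta,3,-,-,-,ER/PR
9,38.9,D,3,-,-,-,D,3,+,+,-,ER/PR
10,31,D,3,-,-,-,D,3,-,-,-,
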