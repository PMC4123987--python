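pair,age,type,grade,er,pr,her2
1,45.9,D,3,+,+,-
2,,D,3,+,+,-
3,,,,+,+,-
4,48.8,D,1,+,+,-
5,43.6,D,3,-,-,-
6,35.3,D,2,+,+,-
7,45.1,D,3,+,+,-
8,41.9,D,2,+,+,
9,43.5,D,1,+,+,-
10,43.7,D,3,+,+,
11,44.9,D,2,-,-,-
12,43.6,D,1,+,-,-
13,40.2,D,3,-,-,+
14,32.5,L,3,+,+,+
15,38.5,D,2,-,+,-
16,37.5,D,3,+,+,-
17,39.3,D,3,+,+,-
18,37.6,D,3,-,-,-
19,36.6,D,3,+,+,+
20,35.4,D,3,-,+,-
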