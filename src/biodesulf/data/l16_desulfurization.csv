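run,A,B,C,D,response
1,1,1,1,1,32.65
2,1,2,2,2,60.15
3,1,3,3,3,58.17
4,1,4,4,4,54.16
5,2,2,3,4,55.26
6,2,1,4,3,57.65
7,2,4,1,2,57.19
8,2,3,2,1,60.76
9,3,3,4,2,65.14
10,3,4,3,1,68.22
11,3,1,2,4,66.17
12,3,2,1,3,68.09
13,4,4,2,3,68.15
14,4,3,1,4,51.23
15,4,2,4,1,50.15
16,4,1,3,2,51.50
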