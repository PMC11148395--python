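dune_id,area_ha,occupied,quality
1,54,1,low
2,20,1,low
3,15,1,low
4,13,0,low
5,12,1,low
6,10,1,low
7,9,0,low
8,8,1,low
9,7,1,low
10,7,0,low
11,6,1,low
12,6,0,low
13,5,1,low
14,5,1,low
15,5,0,low
16,4,1,low
17,4,1,low
18,4,0,low
19,3,1,low
20,3,1,low
21,3,0,low
22,3,0,low
23,2,1,low
24,2,1,low
25,2,1,low
26,2,1,low
27,2,0,low
28,2,0,low
29,1,0,low
30,1,0,low
31,1,0,low
32,1,0,low
33,1,0,low
34,1,0,low
35,1,0,low
36,1,0,low
37,1,0,low
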