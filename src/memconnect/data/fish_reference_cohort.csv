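line,her2_cep17_ratio,her2_mean,cep17_mean,ve1max,ve2max,damax
1,0.4,1.8,4.2,1,1,1
2,0.5,2.1,4.4,1,1,1
3,0.5,1.9,3.5,1,1,1
4,0.9,3.0,3.4,1,1,1
5,1.1,3.7,3.5,1,1,1
6,1.3,4.2,3.3,1,1,1
7,1.7,5.4,3.1,1,1,1
8,1.8,5.7,3.2,1,1,1
9,1.8,7.1,3.9,1,1,1
10,2.1,2.7,1.3,1,1,1
11,2.3,4.2,1.9,1,1,1
12,2.4,3.2,1.3,1,1,1
13,2.7,3.8,1.4,1,1,1
14,4.6,12.6,2.8,1,1,1
15,1.2,1.8,1.6,1,1,2
16,1.3,2.3,1.8,1,1,2
17,1.4,5.7,3.9,1,1,2
18,1.5,6.7,4.5,1,1,2
19,1.6,4.3,2.7,1,1,2
20,1.6,5.3,3.3,1,1,2
21,2.1,3.8,1.8,1,1,2
22,4.5,4.5,1.0,1,1,2
23,0.5,1.5,2.9,1,2,1
24,1.0,2.1,2.1,1,2,2
25,1.3,4.7,3.7,1,2,2
26,1.4,4.1,2.8,1,2,2
27,1.7,5.8,3.5,1,2,2
28,2.0,5.4,2.8,1,2,2
29,2.2,4.3,1.9,1,2,2
30,1.0,4.9,4.7,2,2,2
31,1.1,4.1,3.7,2,2,2
32,1.2,3.0,2.4,2,2,2
33,1.3,5.0,3.8,2,2,2
34,1.4,3.3,2.4,2,2,2
35,1.5,3.3,2.2,2,2,3
36,3.4,11.3,3.4,2,2,3
37,6.5,12.4,1.9,2,3,3
38,1.7,9.0,5.2,3,2,3
39,1.4,2.6,1.8,3,3,3
40,1.5,4.6,3.1,3,3,3
41,2.3,4.3,1.9,3,3,3
42,4.5,4.5,1.0,3,3,3
43,4.7,10.1,2.2,3,3,3
44,4.9,11.2,2.3,3,3,3
45,4.9,15.5,3.2,3,3,3
46,5.4,13.8,2.6,3,3,3
47,5.9,16.8,2.9,3,3,3
48,6.5,20.4,3.2,3,3,3
49,6.8,13.6,2.0,3,3,3
50,7.2,22.7,3.2,3,3,3
51,7.2,23.2,3.2,3,3,3
52,8.3,22.0,2.7,3,3,3
53,13.1,28.2,2.2,3,3,3
54,13.3,38.5,2.9,3,3,3
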