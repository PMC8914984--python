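subject,muscle,seg_1,seg_2,seg_3,seg_n_minus_2,seg_n_minus_1,seg_n
1,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
1,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
2,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
2,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue,Fatigue
3,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
3,right,Not-Examined,Not-Examined,Not-Examined,Not-Examined,Not-Examined,Not-Examined
4,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
4,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
5,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
5,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
6,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
6,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
7,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
7,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
8,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue
8,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
9,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
9,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
10,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
10,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
11,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
11,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
12,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue
12,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
13,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
13,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
14,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
14,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
15,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
15,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
16,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue
16,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
17,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
17,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
18,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
18,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
19,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
19,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
20,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
20,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
21,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
21,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
22,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
22,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
23,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
23,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
24,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
24,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
25,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
25,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue
26,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
26,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
27,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
27,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
28,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
28,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
29,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue,Fatigue
29,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
30,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
30,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
31,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
31,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
32,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
32,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue
33,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
33,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
34,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
34,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
35,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
35,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
36,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
36,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
37,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
37,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue,Fatigue
38,left,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
38,right,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Non-fatigue,Fatigue
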