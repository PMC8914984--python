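subject,muscle,mnf_hz,mdf_hz
1,left,85,73
1,right,84,76
2,left,83,77
2,right,98,90
3,left,88,80
3,right,,
4,left,85,70
4,right,84,73
5,left,88,79
5,right,89,80
6,left,77,72
6,right,89,84
7,left,69,67
7,right,65,63
8,left,89,80
8,right,83,77
9,left,86,73
9,right,96,89
10,left,89,81
10,right,90,83
11,left,86,75
11,right,92,85
12,left,87,80
12,right,89,82
13,left,88,78
13,right,93,84
14,left,83,74
14,right,81,73
15,left,82,74
15,right,84,79
16,left,86,75
16,right,85,76
17,left,82,74
17,right,87,77
18,left,81,74
18,right,92,86
19,left,80,72
19,right,87,81
20,left,79,72
20,right,85,76
21,left,78,70
21,right,84,78
22,left,84,76
22,right,86,78
23,left,83,75
23,right,79,74
24,left,87,79
24,right,72,68
25,left,75,70
25,right,85,75
26,left,86,80
26,right,83,75
27,left,93,86
27,right,83,75
28,left,89,77
28,right,83,76
29,left,77,73
29,right,86,78
30,left,85,80
30,right,90,80
31,left,89,82
31,right,84,75
32,left,82,74
32,right,84,76
33,left,81,75
33,right,85,74
34,left,86,74
34,right,83,76
35,left,85,78
35,right,83,76
36,left,93,88
36,right,79,73
37,left,89,82
37,right,80,72
38,left,87,76
38,right,84,76
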