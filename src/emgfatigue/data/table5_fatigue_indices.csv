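subject,muscle,fatigue_index_first_segment,fatigue_index_last_segment,time_consumed_s
1,left,-0.682,0.063,25
1,right,-0.648,0.072,31
2,left,-0.468,0.006,33
2,right,-0.248,0.003,60
3,left,-0.314,0.010,70
3,right,,,
4,left,-0.122,0.021,94
4,right,-0.142,0.096,100
5,left,-0.300,0.020,51
5,right,-0.266,0.004,113
6,left,-0.239,0.002,109
6,right,-0.558,0.001,115
7,left,-0.126,0.033,67
7,right,-0.253,0.050,75
8,left,-0.203,-0.053,12
8,right,-0.326,0.022,20
9,left,-0.363,0.027,85
9,right,-0.450,0.012,92
10,left,-0.431,0.005,45
10,right,-0.428,0.071,83
11,left,-0.358,0.020,73
11,right,-0.454,0.003,75
12,left,-0.424,-0.012,65
12,right,-0.473,0.023,66
13,left,-0.479,0.037,61
13,right,-0.518,0.012,74
14,left,-0.396,0.019,56
14,right,-0.439,0.033,67
15,left,-0.427,0.009,58
15,right,-0.363,0.045,64
16,left,-0.415,-0.079,52
16,right,-0.340,0.023,92
17,left,-0.352,0.016,52
17,right,-0.523,0.002,78
18,left,-0.392,0.098,52
18,right,-0.560,0.003,69
19,left,-0.521,0.004,49
19,right,-0.482,0.022,65
20,left,-0.438,0.068,41
20,right,-0.398,0.045,56
21,left,-0.425,0.041,44
21,right,-0.438,0.009,68
22,left,-0.145,0.019,94
22,right,-0.245,0.067,100
23,left,-0.488,0.017,67
23,right,-0.134,0.003,83
24,left,-0.257,0.001,85
24,right,-0.490,0.011,95
25,left,-0.130,0.023,53
25,right,-0.290,-0.023,34
26,left,-0.290,0.027,42
26,right,-0.309,0.012,54
27,left,-0.463,0.018,80
27,right,-0.523,0.017,85
28,left,-0.285,0.008,49
28,right,-0.137,0.062,76
29,left,-0.389,0.010,70
29,right,-0.652,0.023,76
30,left,-0.398,0.023,81
30,right,-0.378,0.034,89
31,left,-0.289,0.028,59
31,right,-0.478,0.035,69
32,left,-0.145,0.012,65
32,right,-0.537,-0.059,59
33,left,-0.405,0.047,60
33,right,-0.407,0.063,72
34,left,-0.537,0.059,59
34,right,-0.469,0.033,85
35,left,-0.425,0.006,63
35,right,-0.526,0.032,78
36,left,-0.397,0.048,49
36,right,-0.465,0.063,65
37,left,-0.324,0.055,59
37,right,-0.372,0.034,73
38,left,-0.426,0.056,64
38,right,-0.293,0.036,70
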