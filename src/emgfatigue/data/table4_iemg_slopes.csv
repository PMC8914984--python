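subject,muscle,slope_non_fatigue,slope_fatigue
1,left,-0.0018,0.038
1,right,-0.0038,0.4
2,left,-0.00016,0.14
2,right,-0.0002,1.4
3,left,-0.00081,0.15
3,right,,
4,left,-0.0021,0.057
4,right,-0.0016,0.074
5,left,-0.00021,0.0014
5,right,-0.00001,0.014
6,left,-0.00015,0.33
6,right,-0.00008,0.28
7,left,-0.0017,0.15
7,right,-0.0014,0.098
8,left,-0.0046,0.048
8,right,-0.0043,0.053
9,left,-0.0013,0.27
9,right,-0.00008,0.09
10,left,-0.005,0.087
10,right,-0.0073,0.09
11,left,-0.0002,0.024
11,right,-0.00023,0.059
12,left,-0.0044,0.027
12,right,-0.000013,0.0044
13,left,-0.00067,0.036
13,right,-0.0026,0.21
14,left,-0.00001,0.039
14,right,-0.000005,0.022
15,left,-0.000007,0.045
15,right,-0.00057,0.024
16,left,-0.00023,0.02
16,right,-0.00012,0.019
17,left,-0.0009,0.047
17,right,-0.0022,0.019
18,left,-0.0033,0.085
18,right,-0.00067,0.011
19,left,-0.0006,0.05
19,right,-0.0003,0.05
20,left,-0.00011,0.037
20,right,-0.00004,0.045
21,left,-0.0002,0.203
21,right,-0.00234,0.038
22,left,-0.0018,0.04
22,right,-0.0007,0.8
23,left,-0.00016,0.16
23,right,-0.0002,1.8
24,left,-0.00009,0.6
24,right,-0.0021,0.1
25,left,0.0008,0.08
25,right,-0.00021,0.002
26,left,-0.0056,0.023
26,right,-0.00078,0.23
27,left,-0.0067,0.28
27,right,-0.0067,0.18
28,left,-0.009,0.1
28,right,-0.0067,0.05
29,left,-0.0021,0.06
29,right,0.0034,0.15
30,left,-0.00076,0.1
30,right,-0.0099,0.02
31,left,-0.00045,0.96
31,right,-0.0002,0.024
32,left,-0.0045,0.033
32,right,-0.0045,0.03
33,left,-0.344,0.005
33,right,-0.00067,0.068
34,left,-0.00045,0.2
34,right,-0.00001,0.04
35,left,-0.004,0.05
35,right,-0.0067,0.05
36,left,-0.00057,0.033
36,right,-0.00023,0.02
37,left,-0.0067,0.03
37,right,-0.0006,0.06
38,left,-0.000046,0.035
38,right,-0.0000078,0.019
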