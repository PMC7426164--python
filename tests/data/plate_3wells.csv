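time_min,A1,A2,A3
0,0.050000,0.050000,0.500000
10,0.058092,0.055259,0.500000
20,0.067493,0.061070,0.500000
30,0.078416,0.067493,0.500000
40,0.091106,0.074591,0.500000
50,0.105850,0.082436,0.500000
60,0.122980,0.091106,0.500000
70,0.142883,0.100688,0.500000
80,0.166006,0.111277,0.500000
90,0.192871,0.122980,0.500000
100,0.224084,0.135914,0.500000
110,0.260349,0.150208,0.500000
120,0.302482,0.166006,0.500000
130,0.351434,0.183465,0.500000
140,0.408308,0.202760,0.500000
150,0.474387,0.224084,0.500000
160,0.551159,0.247652,0.500000
170,0.640355,0.273697,0.500000
180,0.743987,0.302482,0.500000
190,0.864389,0.334295,0.500000
200,1.004277,0.369453,0.500000
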