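group_id,volume_robinia_m3,count_robinia,volume_pinus_m3,count_pinus
1,3.51,92,0.24,20
2,2.61,72,0.19,14
3,2.45,95,0.36,18
4,2.89,83,0.17,15
5,3.22,81,0.10,11
6,2.52,74,0.23,16
7,2.94,86,0.25,20
8,2.82,77,0.18,16
9,2.92,91,0.29,16
10,2.16,71,0.23,15
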