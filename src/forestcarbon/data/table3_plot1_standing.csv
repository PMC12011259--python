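group_id,volume_robinia_m3,count_robinia,volume_pinus_m3,count_pinus,volume_elm_m3,count_elm
1,3.82,156,0.31,38,5.54,19
2,1.82,121,0.23,36,5.72,19
3,2.41,122,0.26,38,8.29,21
4,2.43,96,0.19,32,2.78,19
5,2.31,86,0.13,36,19.98,24
6,2.51,95,0.2,35,6.46,19
7,2.46,103,0.18,33,24.94,23
8,1.82,90,0.22,37,17.09,26
9,2.21,105,0.23,34,7.94,22
10,1.35,62,0.19,34,12.92,17
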