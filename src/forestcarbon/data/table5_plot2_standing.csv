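group_id,volume_robinia_m3,count_robinia,volume_pinus_m3,count_pinus,volume_elm_m3,count_elm
1,3.63,128,0.25,23,0.59,51
2,3.45,111,0.22,15,0.86,43
3,2.45,95,0.36,19,0.61,29
4,3.06,120,0.18,16,0.33,39
5,3.38,136,0.11,13,0.11,37
6,3.04,129,0.23,16,0.40,49
7,3.10,121,0.25,21,0.34,47
8,2.99,121,0.18,16,0.24,34
9,3.10,130,0.30,16,0.14,49
10,2.50,124,0.24,15,0.56,45
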