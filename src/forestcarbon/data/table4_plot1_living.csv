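group_id,volume_robinia_m3,count_robinia,volume_pinus_m3,count_pinus
1,4.91,71,0.46,34
2,3.08,71,0.38,32
3,3.25,70,0.41,34
4,3.61,74,0.32,28
5,3.69,85,0.28,32
6,3.31,74,0.35,31
7,3.58,73,0.33,29
8,2.87,69,0.37,32
9,3.38,72,0.38,30
10,2.43,53,0.34,30
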