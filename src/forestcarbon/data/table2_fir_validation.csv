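age,mean_dbh_cm,mean_height_m,predicted_t_hm2,observed_t_hm2,abs_error_printed_t_hm2,rel_error_printed_pct
5,8.75,5.37,19.559,21.099,1.54,7.30
6,9.25,5.97,21.667,24.282,2.615,10.77
7,9.75,6.87,24.749,29.011,4.262,14.69
8,10.35,7.87,28.323,31.023,2.7,8.70
9,11.15,8.27,31.762,33.045,1.283,3.88
10,11.65,8.97,33.591,37.931,4.34,11.44
11,12.15,9.87,36.897,39.971,3.074,7.69
12,12.65,10.07,40.757,41.54,0.783,1.88
13,13.15,10.67,42.778,45.714,2.936,6.42
15,13.65,11.07,44.295,45.934,1.639,3.57
16,14.15,11.77,46.825,48.803,1.978,4.05
17,14.35,11.97,47.902,51.861,3.959,7.63
18,14.75,12.87,50.307,52.017,1.71,3.29
19,14.95,12.87,52.97,53.877,0.907,1.68
20,15.15,13.27,52.081,56.269,4.188,7.44
21,15.45,13.57,54.735,56.141,1.406,2.50
22,15.75,13.97,57.632,57.98,0.348,0.60
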