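plot_id,total_volume_m3,surviving_volume_m3,volume_density_m3_hm2
plot1,24.41,23.74,30.51
plot2,36.00,30.30,45.00
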