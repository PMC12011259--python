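plot_id,biomass_t,carbon_sink_measured_t_hm2,carbon_sink_model_t_hm2
plot1,55.08,21.24,
plot2,56.58,21.65,22.26
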