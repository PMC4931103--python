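instance,energy_mean,energy_sd,time_mean,time_sd
met_enkephalin,-4.3016,0.7410,0.3357,0.2943
proinsulin,-105.8938,10.4815,8.8670,8.1788
T0549,-214.0610,30.3024,46.1749,35.5258
T0335,-304.7289,52.3785,91.6016,76.1357
T0281,-240.9620,54.8912,85.0103,71.3112
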