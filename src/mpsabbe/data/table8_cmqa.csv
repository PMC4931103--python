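instance,energy_mean,energy_sd,time_mean,time_sd
met_enkephalin,-3.7820,0.7848,0.5719,0.4509
proinsulin,-104.7165,10.8593,18.9617,16.2658
T0549,-217.1220,36.7019,121.9018,96.2037
T0335,-311.3921,39.3025,204.2191,154.3906
T0281,-254.3024,42.6025,231.8738,185.2004
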