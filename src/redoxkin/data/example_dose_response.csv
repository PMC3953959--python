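h2o2,fraction
50,0.5168513345
100,0.267135302
200,0.07136126956
500,0.001360368038
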