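condition,mt,frequency_per_um_s
control,0,0.000243818
control,1,0.0
control,2,0.0
control,3,0.000236781
control,4,0.000416323
control,5,0.0
control,6,0.0
control,7,0.0
activated,0,0.001611419
activated,1,0.001493756
activated,2,0.001609013
activated,3,0.001298368
activated,4,0.002460135
activated,5,0.00201494
activated,6,0.001636166
activated,7,0.002649646
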