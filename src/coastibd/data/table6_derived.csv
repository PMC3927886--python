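method,row,low,mean,high
migrate,mean_of_finite,0,7.58,16.36
migrate,ne,0,2632,4.00E05
migrate,de,0.00,1.94,294.12
ldne,mean_of_finite,176.89,895,inf
ldne,ne,176.89,895,inf
ldne,de,0.13,0.66,inf
onesamp,mean_of_finite,2962,4.07E05,4.65E05
onesamp,ne,2962,4.07E05,4.65E05
onesamp,de,2.18,298.98,341.69
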