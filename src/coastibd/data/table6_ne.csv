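method,population,low,mean,high,quantity
migrate,1,0,6.99,17.2,theta
migrate,2,0,7,15.6,theta
migrate,3,0,7.8,16.4,theta
migrate,4,0,7.8,16.4,theta
migrate,5,0,7.4,16,theta
migrate,6,0,7.4,16,theta
migrate,7,0,8.6,17.2,theta
migrate,8,0,8.2,16.8,theta
migrate,9,0,7,15.6,theta
migrate,pooled,0,7.4,16,theta
ldne,1,536,neg,inf,ne
ldne,2,89,342,inf,ne
ldne,3,127,neg,inf,ne
ldne,4,96,545,inf,ne
ldne,5,71,neg,inf,ne
ldne,6,300,1630,inf,ne
ldne,7,95,1063,inf,ne
ldne,8,130,neg,inf,ne
ldne,9,148,neg,inf,ne
ldne,pooled,1530,neg,inf,ne
onesamp,1,6.45E03,7.59E04,inf,ne
onesamp,2,5.74E03,1.14E05,inf,ne
onesamp,3,2.31E03,1.42E04,5.67E05,ne
onesamp,4,neg,2.05E06,inf,ne
onesamp,5,5.80E02,2.20E03,3.76E04,ne
onesamp,6,neg,neg,neg,ne
onesamp,7,1.83E03,1.31E04,1.21E06,ne
onesamp,8,neg,9.82E05,inf,ne
onesamp,9,8.66E02,3.54E03,4.76E04,ne
onesamp,pooled,neg,neg,neg,ne
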