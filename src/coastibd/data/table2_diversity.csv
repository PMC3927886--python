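locus,population,Ho,He,Fis,Fis_p,Ar
Sma7,1,0.286,0.358,0.203,0.013,4.398
Sma7,2,0.420,0.435,0.034,,3.000
Sma7,3,0.575,0.540,-0.064,,4.633
Sma7,4,0.519,0.613,0.154,0.068,4.879
Sma7,5,0.400,0.382,-0.046,,3.000
Sma7,6,0.480,0.457,-0.051,,4.752
Sma7,7,0.527,0.578,0.087,0.018,4.869
Sma7,8,0.417,0.499,0.165,0.081,4.619
Sma7,9,0.533,0.533,-0.001,,6.000
Sme4,1,0.935,0.937,0.002,,19.612
Sme4,2,0.980,0.949,-0.033,,20.668
Sme4,3,0.894,0.957,0.066,0.046,24.600
Sme4,4,0.926,0.955,0.031,,23.313
Sme4,5,1.000,0.947,-0.056,,18.606
Sme4,6,0.943,0.951,0.009,,22.504
Sme4,7,0.873,0.950,0.082,,22.666
Sme4,8,0.878,0.949,0.076,0.034,22.680
Sme4,9,1.000,0.959,-0.043,,22.000
Sme9,1,0.882,0.897,0.017,,16.122
Sme9,2,0.840,0.905,0.072,,16.667
Sme9,3,0.894,0.886,-0.008,,13.884
Sme9,4,0.906,0.899,-0.008,,15.131
Sme9,5,0.824,0.911,0.096,0.063,18.347
Sme9,6,0.873,0.889,0.018,,15.477
Sme9,7,0.873,0.897,0.027,,16.378
Sme9,8,0.959,0.912,-0.051,,15.878
Sme9,9,0.967,0.909,-0.064,,16.000
Spi10,1,0.584,0.635,0.079,,7.809
Spi10,2,0.640,0.615,-0.040,,6.419
Spi10,3,0.468,0.464,-0.008,,6.460
Spi10,4,0.482,0.504,0.045,,8.173
Spi10,5,0.353,0.364,0.029,,4.987
Spi10,6,0.420,0.484,0.133,0.0028,7.167
Spi10,7,0.482,0.503,0.043,,7.183
Spi10,8,0.367,0.408,0.100,,7.482
Spi10,9,0.467,0.537,0.131,,7.000
Spi12,1,0.182,0.170,-0.069,,2.909
Spi12,2,0.180,0.169,-0.063,,2.968
Spi12,3,0.149,0.141,-0.059,,2.637
Spi12,4,0.204,0.191,-0.065,,4.465
Spi12,5,0.177,0.168,-0.050,,3.869
Spi12,6,0.190,0.192,0.014,,3.620
Spi12,7,0.241,0.248,0.028,,2.915
Spi12,8,0.122,0.118,-0.038,,3.204
Spi12,9,0.133,0.129,-0.036,,3.000
Spi4,1,0.299,0.359,0.167,0.015,7.497
Spi4,2,0.460,0.487,0.056,,8.801
Spi4,3,0.404,0.423,0.044,,8.291
Spi4,4,0.537,0.581,0.075,,10.183
Spi4,5,0.429,0.423,-0.014,,7.782
Spi4,6,0.457,0.461,0.008,,9.031
Spi4,7,0.473,0.487,0.029,,7.934
Spi4,8,0.449,0.456,0.016,,9.587
Spi4,9,0.500,0.529,0.055,,11.000
Spi6,1,0.882,0.875,-0.007,,11.284
Spi6,2,0.880,0.849,-0.037,,11.388
Spi6,3,0.870,0.825,-0.054,,8.746
Spi6,4,0.759,0.863,0.12,0.029,10.031
Spi6,5,0.857,0.868,0.012,,12.265
Spi6,6,0.794,0.858,0.074,0.011,11.450
Spi6,7,0.789,0.838,0.059,,10.512
Spi6,8,0.796,0.845,0.058,,11.756
Spi6,9,0.767,0.819,0.064,,9.000
Sth37,1,0.584,0.524,-0.115,,3.165
Sth37,2,0.500,0.513,0.025,,2.600
Sth37,3,0.532,0.515,-0.032,,2.638
Sth37,4,0.574,0.502,-0.143,,2.000
Sth37,5,0.546,0.535,-0.020,,2.993
Sth37,6,0.531,0.521,-0.020,,2.955
Sth37,7,0.455,0.505,0.099,,2.545
Sth37,8,0.653,0.519,-0.259,0.040,3.224
Sth37,9,0.333,0.475,0.298,0.10,2.000
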