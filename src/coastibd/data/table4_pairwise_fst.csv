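pop_i,pop_j,fst,p
1,2,0.0025,0.00278
1,3,0.0063,0.00278
1,4,0.0116,0.00139
1,5,0.0075,0.00139
1,6,0.0051,0.00139
1,7,0.0091,0.00139
1,8,0.0106,0.00139
1,9,0.0137,0.00139
2,3,0.0,0.24861
2,4,0.0015,0.30833
2,5,0.0033,0.03889
2,6,-0.0001,0.08889
2,7,0.0007,0.02361
2,8,0.0043,0.00694
2,9,0.0017,0.00278
3,4,-0.0008,0.8375
3,5,-0.0008,0.1625
3,6,-0.001,0.7625
3,7,0.0004,0.37222
3,8,-0.0022,0.94028
3,9,0.0037,0.14028
4,5,0.0038,0.475
4,6,0.0027,0.59722
4,7,-0.0021,0.81111
4,8,-0.0005,0.98333
4,9,0.0026,0.06944
5,6,-0.0017,0.58194
5,7,0.003,0.12917
5,8,-0.0031,0.70833
5,9,0.0027,0.26944
6,7,0.0019,0.12639
6,8,0.0007,0.52639
6,9,0.0039,0.01667
7,8,0.0008,0.33472
7,9,-0.0003,0.14861
8,9,-0.0004,0.56667
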