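group,animal,n_beats,pressure_type,intercept,slope,r_squared,F
TXA,1,1611,sPAP,70.945,-0.481,0.356,888.151
TXA,1,1611,mPAP,83.645,-0.969,0.499,1601.15
TXA,1,1611,dPAP,49.662,-0.112,0.00885,14.364
TXA,2,686,sPAP,98.938,-1.298,0.502,689.041
TXA,2,686,mPAP,99.054,-1.616,0.466,596.726
TXA,2,686,dPAP,84.597,-1.537,0.430,517.007
TXA,3,333,sPAP,42.133,-0.646,0.547,400.226
TXA,3,333,mPAP,44.194,-0.917,0.534,379.604
TXA,3,333,dPAP,37.053,-0.967,0.542,391.071
TXA,4,377,sPAP,46.632,-0.683,0.399,248.757
TXA,4,377,mPAP,44.595,-0.815,0.210,90.716
TXA,4,377,dPAP,43.850,-1.239,0.245,121.935
TXA,5,426,sPAP,81.659,-2.047,0.649,783.579
TXA,5,426,mPAP,62.936,-1.719,0.597,628.24
TXA,5,426,dPAP,46.610,-1.243,0.447,342.462
TXA,6,440,sPAP,63.723,-0.972,0.765,1422.27
TXA,6,440,mPAP,62.645,-1.129,0.686,955.157
TXA,6,440,dPAP,58.002,-1.188,0.628,738.206
hypoxia,1,686,sPAP,98.938,-1.298,0.502,689.041
hypoxia,1,686,mPAP,99.054,-1.616,0.466,596.726
hypoxia,1,686,dPAP,84.597,-1.537,0.430,517.007
hypoxia,2,1022,sPAP,95.676,-1.501,0.671,2083.98
hypoxia,2,1022,mPAP,90.743,-1.719,0.598,1518.03
hypoxia,2,1022,dPAP,85.160,-2.027,0.503,1030.82
hypoxia,3,444,sPAP,93.021,-1.542,0.597,653.743
hypoxia,3,444,mPAP,93.907,-1.967,0.547,534.506
hypoxia,3,444,dPAP,77.779,-1.806,0.467,386.649
hypoxia,4,1040,sPAP,117.075,-2.902,0.750,3114.64
hypoxia,4,1040,mPAP,97.682,-2.717,0.730,2804.00
hypoxia,4,1040,dPAP,80.169,-2.548,0.709,2531.34
hypoxia,5,290,sPAP,88.233,-1.354,0.716,725.429
hypoxia,5,290,mPAP,74.310,-1.249,0.652,539.333
hypoxia,5,290,dPAP,60.839,-1.024,0.551,354.094
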