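sex,stratum,life_expectancy,lifetime_qalys,mean_ldl,mean_hdl
all,1,80.23,67.55,2.58,1.59
all,2,79.42,66.88,3.58,1.42
all,3,76.90,64.85,3.97,1.19
all,4,63.02,53.87,3.50,0.76
female,1,82.02,68.22,2.63,1.68
female,2,81.46,67.76,3.73,1.49
female,3,79.64,66.31,4.02,1.21
female,4,70.57,59.30,3.45,0.77
male,1,78.45,66.87,2.53,1.50
male,2,77.38,66.00,3.44,1.36
male,3,74.17,63.40,3.93,1.17
male,4,55.48,48.45,3.54,0.74
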