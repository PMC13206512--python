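sex,ldl_group,life_expectancy,lifetime_qalys
all,1,79.58,67.02
all,2,77.07,65.01
all,gt4,69.68,59.08
all,3,73.14,61.86
all,4,66.23,56.29
female,1,81.93,68.16
female,2,80.75,67.22
female,3,78.74,65.65
female,4,74.08,62.01
male,1,77.23,65.88
male,2,73.39,62.79
male,3,67.54,58.07
male,4,58.38,50.57
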