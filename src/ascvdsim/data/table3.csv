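sex,stratum,hf_total,hf_fatal,ihd_total,ihd_fatal,mi_total,mi_fatal,other_fatal,is_total,is_fatal
all,1,13960,1807,4370,3551,5000,2508,85998,10882,5192
all,2,13166,1958,6499,3746,12642,6565,81679,10859,5180
all,3,11212,2298,14686,5557,31163,16797,70178,9031,4424
all,4,4623,1615,55992,19540,73090,46297,30845,2925,1459
female,1,15356,1904,4580,3954,3082,1608,86896,9320,4478
female,2,14682,2022,6258,4028,8256,4350,83818,9710,4656
female,3,13128,2418,12984,5448,21820,11590,75112,8864,4384
female,4,7058,2366,47218,16008,61046,37872,41220,4192,2104
male,1,12564,1710,4160,3148,6918,3408,85100,12444,5906
male,2,11650,1894,6740,3464,17028,8780,79540,12008,5704
male,3,9296,2178,16388,5666,40506,22004,65244,9198,4464
male,4,2188,864,64766,23072,85134,54722,20470,1658,814
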