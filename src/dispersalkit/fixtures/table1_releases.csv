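release_id,date,experience,design_id,n_traps,storage_days_min,storage_days_max,n_placed,n_flew,pct_flew,n_recaptured,pct_recaptured,sex_m_released,sex_f_released,sex_m_recap,sex_f_recap,retained
1,2014-02-03,experienced,D170,170,3,11,1409,875,62.1,2,0.2,10,17,2,0,1
2,2014-02-03,naive,D170,170,1,20,719,468,65.1,9,1.9,11,8,8,1,1
3,2014-02-24,experienced,D170,170,4,20,1997,1142,57.2,4,0.4,16,15,2,2,1
4,2014-02-24,naive,D170,170,1,21,1155,186,16.1,0,0.0,19,12,,,1
5,2014-02-25,experienced,D170,170,1,7,1966,1089,55.4,5,0.5,,,,,1
6,2014-03-18,experienced,D200,200,18,21,796,125,15.7,0,0.0,,,,,0
7,2014-03-18,experienced,D200,200,4,4,1005,431,42.9,17,3.9,26,24,10,7,1
8,2014-03-19,experienced,D200,200,9,9,1550,1110,71.6,34,3.1,25,25,19,15,1
9,2014-03-19,experienced,D200,200,1,1,552,362,65.6,19,5.2,23,29,13,6,1
10,2014-05-01,experienced,D200,200,30,43,1607,90,5.6,0,0.0,16,15,,,0
11,2014-05-01,naive,D200,200,1,48,2111,190,9.0,2,1.1,21,9,,,1
12,2014-05-02,experienced,D200,200,41,,750,3,0.4,0,0.0,13,17,,,0
13,2014-05-02,naive,D200,200,1,1,2196,828,37.7,1,0.1,18,12,1,0,1
14,2014-05-19,naive,D200,200,3,3,2181,1854,85.0,3,0.2,11,26,2,1,1
15,2014-05-20,naive,D200,200,1,1,1612,674,41.8,0,0.0,14,22,,,1
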