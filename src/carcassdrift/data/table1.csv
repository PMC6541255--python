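date,beaches,length_km,TUPU_A,TUPU_J,TUPU_AJ,HOPU,CRAU,MURRE,total,pct_intact,ns_north,ns_south
2016-10-17,NB,10,27,2,0,8,0,2,39,92.3,100,0
2016-10-18,"NB, BB",16.5,6,1,1,0,0,0,8,100,63,37
2016-10-19,NB,10,16,3,0,2,0,1,22,63.6,100,0
2016-10-20,NB,10,16,4,1,4,0,1,26,46.2,100,0
2016-10-21,NB,10,12,4,0,2,0,0,18,61.1,100,0
2016-10-25,"LB, NB",13.1,4,0,0,0,0,0,4,25.0,75,25
2016-10-27,"BB, LB, PB",11.5,72,0,4,0,0,7,83,85.5,0,100
2016-11-01,"LB, PB",5,43,1,0,0,0,3,47,68.1,0,100
2016-11-15,"BB, NB",16.5,37,0,0,0,8,0,45,60.0,80,20
2016-11-18,"LB, PB",5,10,0,0,0,1,1,12,0,0,100
2016-11-23,"NB, BB",16.5,17,0,1,0,3,0,21,57.1,71,29
2016-12-07,"NB, BB",16.5,2,0,1,0,3,0,6,33.3,100,0
2017-01-03,"NB, BB",16.5,0,0,0,0,13,0,13,100,38,62
2017-01-11,LB,3.1,0,0,0,0,13,0,13,84.6,0,100
2017-02-03,LB,1.0,0,0,0,0,0,2,2,0,0,100
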