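run,asn_mg_l,glu_mg_l,pro_mg_l,titer_mean,titer_sd,n_reps
1,50,280,140,11866.6,287.8,3
2,65,380,80,10967.8,277.3,3
3,80,260,185,12627.2,279.3,3
4,95,360,125,12429.8,289.6,3
5,110,240,65,12496.7,287.3,3
6,125,340,170,13057.1,282.6,3
7,140,220,110,12604.6,276.3,3
8,155,320,50,12519.1,285.5,3
9,170,200,155,11890.0,274.6,3
10,185,300,95,12706.5,276.4,3
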