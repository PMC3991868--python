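run,asn_mg_l,glu_mg_l,pro_mg_l,titer_mean,titer_sd,n_reps
1,50,200,125,11668.6,276.1,3
2,50,300,50,10763.5,279.8,3
3,50,380,180,10850.6,277.3,3
4,125,200,50,12100.5,277.0,3
5,125,300,125,13064.1,275.9,3
6,125,380,180,12570.8,274.9,3
7,180,200,180,11856.0,171.4,3
8,180,300,125,12878.3,272.9,3
9,180,380,50,12363.2,268.6,3
10,100,333,200,12215.8,272.7,3
11,175,233,175,12143.9,274.1,3
12,50,400,150,10108.0,274.4,3
13,200,200,100,11922.0,275.6,3
14,75,366,75,10914.9,282.2,3
15,150,266,50,12244.3,271.2,3
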