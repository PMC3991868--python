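run,ann_prediction,ud_prediction
1,12085,10647.9
2,11481,11255.8
3,10439,10696.4
4,12128,11533.6
5,13074,13451.9
6,12381,12245.0
7,11778,11656.8
8,12950,12968.4
9,11863,11153.5
10,12068,12787.5
11,12288,12527.9
12,9910,10197.3
13,11675,11066.0
14,11232,11551.1
15,12532,12649.5
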