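run,ann_prediction,ud_prediction
1,11866,11928.7
2,10966,10978.9
3,12622,12608.0
4,12419,12458.5
5,12492,12493.4
6,13048,13110.6
7,12602,12625.8
8,12513,12589.4
9,11893,11930.7
10,12702,12694.6
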