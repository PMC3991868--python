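factor,c_minus2,c_minus1,c_0,c_plus1,c_plus2
asn_mg_l,50,83.75,117.5,151.25,185
glu_mg_l,200,245,290,335,380
pro_mg_l,50,83.75,117.5,151.25,185
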