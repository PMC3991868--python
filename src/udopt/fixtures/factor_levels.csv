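factor,unit,level_1,level_2,level_3,level_4,level_5,level_6,level_7,level_8,level_9,level_10
asn_mg_l,mg/L,50,65,80,95,110,125,140,155,170,185
glu_mg_l,mg/L,200,220,240,260,280,300,320,340,360,380
pro_mg_l,mg/L,50,65,80,95,110,125,140,155,170,185
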