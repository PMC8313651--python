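patient,TB,RMB,LMB,RULB,RMLB,RLLB,RB1,RB2,RB3,RB4,RB5,RB6,RB8,RB9,RB10,LULB,LLLB,LB1/2,LB3,LB4,LB5,LB6,LB8,LB9,LB10,score
p01,16,7,7,3,3,3,0,1,1,0,1,1,1,0,0,3,3,0,0,0,0,1,1,1,1,54
p03,16,7,7,3,3,3,0,1,1,1,1,1,1,1,1,3,3,1,1,1,1,1,1,1,1,61
p04,16,7,7,3,3,3,0,1,1,0,1,1,1,1,1,3,3,1,1,1,1,0,1,1,1,59
p05,8,7,7,3,3,3,1,1,0,1,0,1,1,1,1,3,3,1,1,1,1,1,1,1,1,52
p06,8,7,7,3,3,3,0,1,1,1,1,1,1,1,1,3,3,1,0,1,1,1,1,1,1,52
p07,16,7,7,3,3,3,1,1,1,1,1,1,1,1,1,3,3,1,1,1,1,1,1,1,1,62
p08,16,7,7,3,3,3,1,1,1,1,1,1,1,1,1,3,3,1,1,NA,NA,1,1,1,1,60
p09,8,7,7,3,3,3,1,1,1,1,1,1,0,1,1,3,3,1,1,NA,NA,1,1,1,1,51
p10,8,7,7,3,NA,NA,1,0,0,NA,NA,NA,NA,NA,NA,3,3,1,0,0,0,1,1,1,1,37
p11,8,7,7,3,3,3,1,1,1,1,1,1,0,0,1,3,3,1,0,0,0,1,1,1,1,49
p12,16,7,7,3,3,3,1,1,1,1,1,1,1,1,1,3,3,1,1,1,1,1,1,1,1,62
p13,16,7,7,3,3,3,1,1,1,1,1,1,1,0,1,3,3,1,1,0,0,1,1,1,1,59
p14,16,7,7,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,30
p15,16,7,7,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,30
p16,8,7,7,3,3,3,1,1,1,1,1,1,0,1,1,3,3,1,1,1,1,1,1,1,1,53
p17,16,7,7,3,3,3,1,1,1,1,1,1,0,1,1,3,3,1,1,0,0,1,0,1,1,58
p18,16,7,7,NA,0,0,NA,NA,NA,1,1,1,1,1,1,3,3,1,1,1,1,1,1,1,1,50
p20,8,7,7,3,3,3,1,1,1,1,1,1,1,1,1,3,3,1,1,1,1,1,1,1,1,54
p21,16,7,7,3,3,3,0,1,1,1,1,0,1,1,1,3,3,1,1,1,1,1,1,1,1,60
p22,16,7,7,3,3,3,1,1,1,1,1,1,1,1,1,3,3,1,1,1,1,1,1,1,1,62
p23,16,7,7,3,3,3,1,1,1,1,1,1,1,1,1,3,3,1,1,1,1,1,1,1,1,62
p25,8,7,7,3,3,3,1,1,1,1,1,1,1,1,1,3,3,0,0,0,0,1,0,1,1,49
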