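patient,TB,RMB,LMB,RULB,RMLB,RLLB,RB1,RB2,RB3,RB4,RB5,RB6,RB8,RB9,RB10,LULB,LLLB,LB1/2,LB3,LB4,LB5,LB6,LB8,LB9,LB10
p01,1.7,0.7,0.9,1,1,1,NA,1,1,0,1,1,1,0,0,1,1,0,0,NA,NA,1,1,1,1
p03,0,0,1.1,1,1,1,NA,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1
p04,0,0.5,0.8,1,1,1,NA,1,1,0,1,1,1,1,1,1,1,1,1,1,1,0,1,1,1
p05,2,1.1,0,1,1,1,1,1,0,1,0,1,1,1,1,1,1,1,1,1,1,1,1,1,1
p06,1.9,0,0.4,1,1,1,NA,1,1,1,1,1,1,1,1,1,1,1,0,1,1,1,1,1,1
p07,1.2,0,0,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1
p08,0,0,0,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,NULL,NULL,1,1,1,1
p09,2.6,0,0,1,1,1,1,1,1,1,1,1,NA,1,1,1,1,1,1,NULL,NULL,1,1,1,1
p10,1.9,0,0,1,NULL,NULL,1,0,0,NULL,NULL,NULL,NULL,NULL,NULL,1,1,1,0,NA,NA,1,1,1,1
p11,2.4,0,0,1,1,1,1,1,1,1,1,1,0,NA,1,1,1,1,NA,NA,NA,1,1,1,1
p12,1.1,0,0,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1
p13,1.5,0,0,1,1,1,1,1,1,1,1,1,1,NA,1,1,1,1,1,NA,NA,1,1,1,1
p14,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
p15,1,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
p16,2.5,0,0,1,1,1,1,1,1,1,1,1,NA,1,1,1,1,1,1,1,1,1,1,1,1
p17,0,0,0,1,1,1,1,1,1,1,1,1,0,1,1,1,1,1,1,0,0,1,0,1,1
p18,0,0,0,NULL,0,0,NULL,NULL,NULL,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1
p20,2.8,0,0,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1
p21,0,0,0,1,1,1,NA,1,1,1,1,NA,1,1,1,1,1,1,1,1,1,1,1,1,1
p22,0,0,0,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1
p23,0,0,0,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1
p25,2.3,0,0,1,1,1,1,1,1,1,1,1,1,1,1,1,1,NA,NA,NA,NA,1,NA,1,1
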