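patient,score,pearson,mi,nmi,hkl,l1norm_x1e-7,l2norm2_x1e-10
p01,54,0.86,0.44,1.21,0.44,20.55,13.61
p03,61,0.25,0.25,1.1,0.74,4.1,2.07
p04,59,0.74,0.44,1.21,0.62,15.1,10.4
p05,52,0.32,0.32,1.11,0.55,8.18,5.42
p06,52,0.31,0.31,1.11,0.74,5.89,3.45
p07,62,0.24,0.25,1.09,0.78,4.36,2.34
p08,60,0.28,0.28,1.1,0.8,4.71,2.45
p09,51,0.19,0.19,1.08,0.85,3.11,1.41
p10,37,0.19,0.2,1.09,0.76,4.75,2.5
p11,49,0.24,0.22,1.1,0.79,6.8,4.1
p12,62,0.47,0.47,1.17,0.79,5.35,2.88
p13,59,0.17,0.18,1.07,0.68,6.47,4.21
p14,30,0.15,0.15,1.06,0.75,7.03,4.15
p15,30,0.1,0.1,1.04,0.75,4.67,2.34
p16,53,0.41,0.31,1.13,0.69,10.52,6.87
p17,58,0.34,0.34,1.12,0.69,7.12,4.62
p18,50,0.2,0.2,1.08,0.84,3.83,1.58
p20,54,0.21,0.21,1.08,0.7,8.24,5.2
p21,60,0.43,0.43,1.17,0.8,12.47,1.08
p22,62,0.41,0.41,1.19,0.8,3.97,1.75
p23,62,0.22,0.22,1.08,0.62,10.57,7.32
p25,49,0.26,0.26,1.09,0.44,7.8,5.08
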