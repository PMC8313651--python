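parameter,p,corr,ci_lower,ci_upper
pearson,0.0673,0.3971,-0.0295,0.7013
mi,0.0033,0.5981,0.2360,0.8143
nmi,0.0150,0.5115,0.1146,0.7676
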