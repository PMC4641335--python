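construct,n,PPV,NPV,alpha,corr,corr_method,p
self_efficacy,20,50.0,90.0,0.861,0.418,spearman,0.001
coping,18,41.5,94.4,N.A.,N.A.,N.A.,N.A.
coping (D),18,N.A.,N.A.,0.560,0.783,spearman,0.001
coping (E),18,N.A.,N.A.,0.730,0.800,spearman,0.001
coping (P),18,N.A.,N.A.,0.700,0.746,spearman,0.001
burden,19,N.A.,N.A.,N.A.,0.554,spearman,0.003

regression,beta,SE_beta,standardized_beta,p,r_squared,n
intercept,34.500,,,,,20
self_efficacy,16.430,2.820,0.460,0.000,0.317,20
social_support,6.640,3.060,0.160,0.032,0.317,20
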