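statistic_id,tau1,tau2,alpha,method,n_or_grid,reps,seed,critical_value
sn,0.15,0.85,0.1,finite_sample,1000,50000,1,28.676482748113287
sn,0.15,0.85,0.05,finite_sample,1000,50000,1,33.2335295684631
sn,0.15,0.85,0.01,finite_sample,1000,50000,1,43.19324373821192
sn,0.15,0.85,0.1,limit_functional,1000,50000,2,28.880123326063906
sn,0.15,0.85,0.05,limit_functional,1000,50000,2,33.53283278254802
sn,0.15,0.85,0.01,limit_functional,1000,50000,2,43.839414767746185
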