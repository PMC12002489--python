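group,param,estimate,se,ci_lo,ci_hi,df
all,linf,38.85,0.62,37.77,40.19,1096
all,k,0.15,0.01,0.13,0.17,1096
all,t0,-3.66,0.24,-4.16,-3.22,1096
females,linf,39.58,0.96,36.95,41.78,542
females,k,0.14,0.01,0.12,0.16,542
females,t0,-3.97,0.37,-4.76,-3.31,542
males,linf,38.14,0.80,36.74,39.96,551
males,k,0.16,0.01,0.14,0.19,551
males,t0,-3.36,0.32,-4.03,-2.78,551
celestun,linf,41.59,5.95,34.37,59.72,316
celestun,k,0.11,0.04,0.05,0.20,316
celestun,t0,-4.86,1.15,-7.14,-3.05,316
dzilam,linf,38.36,0.93,36.80,40.65,380
dzilam,k,0.16,0.02,0.13,0.20,380
dzilam,t0,-3.25,0.48,-4.34,-2.42,380
rio_lagartos,linf,40.28,1.35,38.11,43.73,394
rio_lagartos,k,0.12,0.02,0.09,0.15,394
rio_lagartos,t0,-4.99,0.57,-6.28,-4.00,394
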