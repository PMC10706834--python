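actual_pct,ddpcr_mean_pct,ddpcr_sd,qpcr_mean_pct,qpcr_sd,ddpcr_rsd_pct,qpcr_rsd_pct,n
20,20.79,0.48,17.76,1.75,2.29,9.85,4
40,41.32,0.36,45.11,3.10,0.87,6.88,4
60,58.65,0.33,53.73,2.73,0.56,5.08,4
80,79.52,0.44,73.58,3.28,0.55,4.46,4
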