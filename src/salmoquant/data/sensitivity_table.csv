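trout_mass_fraction_pct,measured_mean_pct,measured_sd,rsd_pct,detection_rate_pct,deviation_pct,n
0.05,0,,,0,-100,4
0.1,0.15,0.12,81.28,75.00,51.71,4
0.2,0.36,0.08,22.78,100,81.89,4
0.5,0.37,0.03,8.85,100,-25.52,4
0.8,0.76,0.06,6.36,100,-4.52,4
1,1.15,0.05,4.46,100,15.28,4
5,5.51,0.31,5.71,100,10.10,4
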