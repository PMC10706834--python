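trout_mass_fraction_pct,q_o_mean_copies_per_ul,q_o_sd,q_s_mean_copies_per_ul,q_s_sd,n,k_printed
10,94.00,0.89,376.5,2.88,6,0.44
30,101.23,4.87,97.79,1.68,6,0.41
50,121.30,2.87,51.57,1.51,6,0.43
70,183.50,1.87,34.78,0.86,6,0.44
90,226.50,2.74,11.13,0.77,6,0.44
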