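# Reference performance-metric panel: hardware-in-loop benchmark runs,
# starting MAP 55 mmHg, target 65 mmHg, 10 mL/min hemorrhage, 30 min.
config,mdpe,mdape,mdape_ss,target_overshoot,effectiveness,wobble,divergence,rise_time,mean_inf,area_above,area_below,max_rate_change,var_inf_rate
pid_aggressive,1.04,1.84,1.38,8.04,92.49,1.77,0.76,1.17,0.61,0.71,-0.24,0.0041,0.0155
pid_conservative,-0.18,0.38,0.33,3.00,93.32,0.29,3.46,1.75,0.50,0.10,-0.36,0.0020,0.0154
stepfis_aggressive,14.13,14.18,11.00,21.23,5.01,1.48,-28.51,0.50,1.00,4.09,-0.10,0.0167,0.0000
stepfis_conservative,0.33,0.53,0.40,6.34,96.94,0.56,0.89,0.75,0.63,0.47,-0.16,0.0086,0.0070
anfis_aggressive,4.33,4.35,4.34,4.80,97.49,0.23,-2.73,0.58,0.41,1.22,-0.12,0.0065,0.0008
anfis_conservative,0.09,0.15,0.15,0.36,97.77,0.13,0.06,0.58,0.32,0.03,-0.13,0.00,0.0008
adrc_aggressive,1.59,1.90,1.71,8.14,92.48,1.54,35.47,1.09,0.55,0.77,-0.18,0.0041,0.0155
adrc_conservative,0.21,0.40,0.37,2.08,93.05,0.35,2.18,1.75,0.50,0.11,-0.33,0.0020,0.0160
pfc_aggressive,1.58,1.86,1.78,5.23,97.49,1.63,34.16,0.50,0.60,0.54,-0.17,0.0083,0.0067
pfc_conservative,0.55,1.26,1.16,5.76,97.78,1.33,1.92,0.50,0.54,0.39,-0.24,0.0048,0.0057
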