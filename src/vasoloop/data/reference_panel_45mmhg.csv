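# Reference performance-metric panel: hardware-in-loop benchmark runs,
# starting MAP 45 mmHg, target 65 mmHg, 10 mL/min hemorrhage, 30 min.
config,mdpe,mdape,mdape_ss,target_overshoot,effectiveness,wobble,divergence,rise_time,mean_inf,area_above,area_below,max_rate_change,var_inf_rate
pid_aggressive,2.25,3.16,2.63,6.15,89.97,1.72,13.30,2.75,1.04,0.71,-0.70,0.0041,0.0219
pid_conservative,-0.53,1.16,0.94,3.21,83.84,1.11,2.58,4.34,0.85,0.20,-1.17,0.0020,0.0208
stepfis_aggressive,7.02,7.60,7.42,11.05,50.97,1.78,-17.15,2.00,1.17,2.00,-0.45,0.0171,0.0028
stepfis_conservative,0.07,0.23,0.20,0.97,92.75,0.20,2.62,2.00,0.83,0.05,-0.50,0.0086,0.0115
anfis_aggressive,0.42,0.50,0.46,1.19,93.32,0.23,-1.01,1.84,0.69,0.13,-0.43,0.0108,0.0030
anfis_conservative,-0.03,0.25,0.21,0.51,91.36,0.20,-0.17,1.67,0.59,0.03,-0.60,0.0044,0.0044
adrc_aggressive,0.28,0.62,0.47,3.14,89.97,0.50,7.09,2.75,0.92,0.21,-0.70,0.0041,0.0237
adrc_conservative,-0.04,0.32,0.24,1.19,83.84,0.24,-5.12,4.26,0.82,0.05,-1.10,0.0020,0.0222
pfc_aggressive,0.79,1.32,1.13,3.24,89.69,0.86,-13.47,2.92,1.02,0.30,-0.60,0.0083,0.0219
pfc_conservative,-1.08,1.08,0.63,0.75,76.60,0.58,-31.31,6.76,0.83,0.01,-1.46,0.0042,0.0238
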