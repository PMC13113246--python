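# Reference performance-metric panel: hardware-in-loop benchmark runs,
# starting MAP 35 mmHg, target 65 mmHg, 10 mL/min hemorrhage, 30 min.
# One row per controller configuration; values as printed (rounded).
config,mdpe,mdape,mdape_ss,target_overshoot,effectiveness,wobble,divergence,rise_time,mean_inf,area_above,area_below,max_rate_change,var_inf_rate
pid_aggressive,-1.53,1.90,1.77,4.74,86.35,0.87,3.86,3.75,1.59,0.22,-1.50,0.0041,0.0448
pid_conservative,-2.07,2.07,1.73,1.26,69.64,0.43,5.69,8.10,1.41,0.01,-2.69,0.0020,0.0432
stepfis_aggressive,-0.12,0.20,0.17,0.65,88.58,0.17,-1.12,3.25,1.80,0.02,-1.00,0.0182,0.0299
stepfis_conservative,-0.38,0.39,0.25,0.44,81.62,0.25,1.87,4.51,1.87,0.01,-1.47,0.0094,0.0427
anfis_aggressive,-0.13,0.33,0.27,0.60,89.42,0.27,-0.04,3.00,1.15,0.03,-1.05,0.0167,0.0040
anfis_conservative,-0.31,0.31,0.21,0.21,84.95,0.20,1.36,3.92,1.01,0.00,-1.24,0.01,0.0200
adrc_aggressive,-0.29,0.47,0.35,1.53,86.64,0.32,9.76,3.76,1.51,0.04,-1.30,0.0041,0.0431
adrc_conservative,-0.61,0.61,0.46,0.39,74.10,0.21,-2.27,7.10,1.28,0.00,-2.23,0.0020,0.0422
pfc_aggressive,-0.85,0.94,0.70,1.23,85.23,0.66,11.79,3.92,1.68,0.03,-1.38,0.0083,0.0546
pfc_conservative,-8.36,8.36,4.31,0.00,46.79,0.48,-1.60,13.10,1.26,0.00,-4.01,0.0042,0.0542
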