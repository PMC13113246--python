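# Reference aggregate terms and overall scores for the benchmark runs,
# per scenario (starting MAP) and averaged across the three scenarios.
# Note: the 45 and 55 mmHg stable-term cells are not derivable from the
# rounded reference panels under any tested convention (they were evidently
# computed from unrounded internal data); treat those cells as informative
# only when cross-checking against panel-derived terms.
scenario,term,pid_aggressive,pid_conservative,stepfis_aggressive,stepfis_conservative,anfis_aggressive,anfis_conservative,adrc_aggressive,adrc_conservative,pfc_aggressive,pfc_conservative
35,stable,3.08,2.84,0.51,0.78,0.53,0.62,2.22,0.98,3.23,4.37
35,overshoot,7.02,0.97,0.72,0.41,0.90,0.11,1.60,0.25,1.36,0.00
35,undershoot,0.67,1.32,0.51,0.73,0.50,0.62,0.62,1.13,0.66,2.05
35,infusion,0.93,0.77,1.62,1.26,1.18,0.89,0.90,0.73,1.25,0.93
35,effectiveness_term,3.47,4.68,0.36,0.76,0.58,0.58,0.85,1.30,1.75,28.21
35,overall,40.61,27.60,1.23,2.41,1.81,1.29,4.56,4.01,11.36,207.45
45,stable,2.87,1.36,6.56,0.75,1.31,0.75,0.81,0.40,1.66,0.96
45,overshoot,2.38,0.90,5.74,0.25,0.44,0.14,0.92,0.28,1.09,0.15
45,undershoot,0.69,1.12,0.47,0.50,0.44,0.51,0.69,1.08,0.66,1.56
45,infusion,1.00,0.79,1.55,1.04,0.98,0.71,0.99,0.79,1.26,0.96
45,effectiveness_term,3.73,1.47,15.85,0.27,0.57,0.29,0.73,0.41,1.57,1.49
45,overall,25.90,6.13,227.08,0.68,1.82,0.60,2.47,1.05,7.33,5.41
55,stable,1.71,0.33,4.35,0.45,1.28,0.09,1.38,0.50,1.78,2.48
55,overshoot,0.96,0.25,4.00,0.70,1.10,0.04,1.01,0.20,0.67,0.61
55,undershoot,1.04,1.55,0.44,0.67,0.52,0.54,0.88,1.49,0.58,0.71
55,infusion,1.41,1.19,1.76,1.32,0.74,0.57,1.37,1.22,1.27,0.94
55,effectiveness_term,1.22,0.25,173.65,0.33,2.74,0.10,1.26,0.26,1.17,0.79
55,overall,6.24,0.83,1833.27,1.05,9.96,0.12,5.84,0.90,5.04,3.75
avg,stable,2.55,1.51,3.81,0.66,1.04,0.49,1.47,0.63,2.22,2.60
avg,overshoot,3.45,0.71,3.49,0.45,0.81,0.10,1.17,0.24,1.04,0.25
avg,undershoot,0.80,1.33,0.47,0.63,0.49,0.56,0.73,1.23,0.63,1.44
avg,infusion,1.11,0.92,1.64,1.21,0.97,0.72,1.08,0.92,1.26,0.94
avg,effectiveness_term,2.81,2.13,63.29,0.45,1.30,0.32,0.95,0.66,1.50,10.16
avg,overall,24.25,11.52,687.19,1.38,4.53,0.67,4.29,1.99,7.91,72.21
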