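# Norepinephrine dosing ladder used during hemorrhage resuscitation;
# single solution concentration 4.0 mcg/mL, so dose = rate x concentration.
step,dose_mcg_min,rate_ml_min
1,0.5,0.13
2,1,0.25
3,2,0.5
4,4,1
5,8,2
6,12,3
7,16,4
8,20,5
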