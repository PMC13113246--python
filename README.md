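# vasoloop

Closed-loop vasopressor titration — the automated adjustment of a
norepinephrine (NE) infusion to hold mean arterial pressure (MAP) at a
therapeutic target during hemorrhagic shock — is an active area of
critical-care automation. `vasoloop` is a software benchtop for that
problem: a virtual hemorrhaging patient whose MAP responds to NE dosing,
five physiological closed-loop controller (PCLC) architectures in
aggressive and conservative tunings, a thirteen-metric performance suite,
and a median-normalized aggregate score used to rank controllers. It is
intended for controls and biomedical engineers who want to compare
titration strategies reproducibly before any hardware or animal testing.

## The model and the score

**Virtual patient.** MAP follows a first-order relaxation toward a
saturating dose–response with a continuous hemorrhage drift:

    dm/dt = [ (B − H(t)) + E(d) + s(t) − m ] / τ − dH/dt
    E(d)  = Emax · d / (d50 + d)

where `B` is the baseline MAP, `H(t)` the cumulative bleed-induced
pressure deficit, `d` the infusion rate active after a lag `L`, `s(t)` a
decaying overshoot transient, and `τ` the responsiveness time constant.
This realizes the four response features characterized for vasopressor
dosing in vivo: lag time, overshoot, steady-state ("real") response, and
responsiveness.

**Controllers.** PID (delayed-error filter `P += (Δt/τ)(P_meas − P)` with
τ = 15 s, anti-windup, slew limiter); Step-FIS (Sugeno fuzzy rules driving
±unit-step rate changes with error-adaptive step size); AN-FIS (trained
first-order Sugeno network, 9 rules, generalized-bell memberships, hybrid
least-squares/backpropagation learning, safeguarded output scaling); ADRC
(tracking differentiator, third-order extended state observer, control law
`u = (kp(v1 − z1) − kd·z2 − z3)/b`); and a patient-following controller
(PFC) that steps the dose only when the smoothed error gradient shows the
current dose's effect has saturated.

**Metrics and score.** Per run: MDPE, MDAPE, MDAPE at steady state, target
overshoot, effectiveness (% time within ±5 mmHg), wobble, divergence, rise
time, mean infusion rate, areas above/below target, maximum smoothed rate
change, and windowed rate variability (performance error
`PE = 100·(m − target)/target`). Per scenario, each metric is normalized
to its median |value| across the ten configurations and grouped:

    Stable     = (MDAPE_SS + Wobble + |Divergence|) / 3
    Overshoot  = (TargetOvershoot + AreaAbove) / 3
    Undershoot = (RiseTime + |AreaBelow|) / 3
    Infusion   = (MeanInf + MaxRateChange + VarInfRate) / 3
    Overall    = (Stable + Overshoot + Undershoot + Infusion) × MDAPE/Effectiveness

Lower is better; overall scores are averaged across the three scenarios
(starting MAP 35, 45, 55 mmHg; target 65 mmHg; 10 mL/min hemorrhage;
30 min runs).

## Worked example

Run the full battery — 10 controller configurations × 3 scenarios — and
rank by study-average aggregate score:

```python
from vasoloop.runner import run_battery
result = run_battery(seed=0)
print(result.summary())
```

prints:

```
study-average overall scores (lower is better):
   1. adrc_conservative              1.12
   2. adrc_aggressive                1.15
   3. anfis_conservative             2.70
   4. anfis_aggressive               3.45
   5. stepfis_aggressive             4.09
   6. stepfis_conservative           4.72
   7. pid_conservative              21.85
   8. pfc_aggressive                27.21
   9. pid_aggressive                28.95
  10. pfc_conservative              90.52
```

Conservative tunings outrank their aggressive counterparts for most
architectures, and the PFC conservative profile — which never reaches
target in the 35 mmHg scenario — is the clear straggler. Individual panels
are in `result.panels[35]` etc.; for example the 35 mmHg scenario row for
the ADRC conservative profile reads MDPE −1.03 %, effectiveness 66.1 %,
rise time 9.4 min, zero overshoot, mean infusion 1.70 mL/min.

The same pipeline is scriptable from the shell:

```sh
vasoloop battery --seed 0 --out-dir out/
vasoloop simulate --controller adrc_conservative --start-map 35 --out run.csv
vasoloop score --out terms.csv           # score the packaged benchmark panels
vasoloop sensitivity --out ranks.csv     # weight-perturbation re-ranking
```

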