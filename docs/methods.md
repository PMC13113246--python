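# Methods

## The virtual patient

The plant stands in for a hardware flow-loop test platform whose valve
module reproduces four features of the in vivo MAP response to
norepinephrine: lag time, overshoot, steady-state response, and
responsiveness. The platform's internal transfer functions are not public,
so the governing equation here is the simplest form that realizes all four
features:

    dm/dt = [ (B − H(t)) + E(d_active) + s(t) − m ] / τ − dH/dt,
    E(d) = Emax·d/(d50 + d)

* **Lag** — a commanded infusion-rate change becomes `d_active` only after
  `lag_time` (default 15 s); pending changes are queued with their
  effective times.
* **Responsiveness** — first-order relaxation with `τ = 60 s`.
* **Real response** — the Emax dose–response; `Emax = 60 mmHg`,
  `d50 = 1.5 mL/min`.
* **Overshoot** — at each effective dose change a transient
  `s += overshoot_frac·ΔE` is injected and decays with `overshoot_tau`
  (120 s); `overshoot_frac = 0.10` by default, `0` gives a monotone
  first-order response. The transient peak is approximately, not exactly,
  `(1 + overshoot_frac)` times the steady-state change, because the
  first-order state chases a decaying target.

**Hemorrhage** is a constant pressure drift `dH/dt = slope × bleed rate`
subtracted from both the state and the relaxation attractor, so at zero
dose the MAP falls at exactly the drift rate from t = 0. The
volume-to-pressure slope (0.03 mmHg/mL) was calibrated so that holding the
65 mmHg target against the 10 mL/min bleed requires ≈1.5 mL/min at the
start and ≈2.8 mL/min at the end of a 30 min run from a 35 mmHg baseline —
in the middle of the discrete dosing ladder (0.13–5 mL/min at 4.0 mcg/mL)
and consistent with mean infusion rates near 1–2 mL/min for well-behaved
controllers.

Integration is explicit Euler at `dt = 0.25 s`; the integration error of
this first-order system at that step is far below physiological noise.
Noise is off by default; when enabled it is Gaussian with
`sd·sqrt(dt)` per step and an explicit seed (`numpy.random.default_rng`).
MAP is clamped to [5, 200] mmHg. Measurements are zero-order-held at the
controller tick (default 10 s), emulating down-sampled non-invasive
pressure readings.

## Controllers

All ten profiles live in `vasoloop/data/default_config.yaml`. Gains that
the underlying study does not print (PID gains, ADRC constants, fuzzy
membership breakpoints) were tuned against the default plant and are
config, not claimed reproductions.

**PID.** Error = target − P_delayed with the first-order delay filter
(τ = 15 s). Anti-windup is twofold: inside the ±5 mmHg band the integral
accumulator is multiplied by 0.998 per 10 s tick (a gentler per-tick decay
than a 1 Hz loop would use, matching the same decay *rate*); outside the
band, integration is frozen whenever the commanded change exceeds the slew
limit — without this the accumulator winds up during the climb and the
loop limit-cycles. Aggressive and conservative profiles differ only in the
per-tick rate limiter (0.1 vs 0.05 mL/min), which is exactly how the two
PID tunings are described for this problem.

**Step-FIS.** First-order Butterworth prefilter (0.02 Hz at the 0.1 Hz
tick; the 0.05 Hz default applies to faster ticks — at 10 s ticks 0.05 Hz
is the Nyquist frequency and is rejected). Signed percent-of-target error
and its rate enter a five-rule Sugeno system over Z-shaped / triangular /
S-shaped memberships. Rule strength is the min of antecedent memberships;
the rule *weight* attenuates the consequent while normalization uses
unweighted strengths, so a lone firing of the weight-0.75 Decrease rule
yields −0.75 — the attenuated decrease plateau of the control surface.
Output above +1/3 steps the rate up, below −1/3 down, else hold; the base
step (0.035/0.025 mL/min) doubles above 30 % |error| and halves below 3 %
(percent of target). The system is implemented as type-1 Sugeno; no
interval type-2 footprint parameters are available to reproduce.

**AN-FIS.** Two inputs (percent-of-target error, positive below target,
and its rate), three generalized-bell memberships each, 9 rules with
first-order consequents. Hybrid training alternates an exact least-squares
consequent solve (ridge fallback if rank deficient; the LS step can never
raise the training RMSE, asserted per epoch) with a central-difference
gradient step on the 18 premise parameters; 70/30 train/test split,
≤100 epochs with early stopping. The shipped model
(`data/anfis_model.json`, schema v1) is trained on plant dose-sweep traces
labelled by a smooth logistic teacher policy
`d = 3.5·σ((e + 25·ė − 3.71)/3.5)` calibrated to the plant's equilibrium
doses; a clamped-linear teacher fits the 9-rule network poorly and was
rejected (test RMSE 0.27 → 0.058 mL/min). The animal training data behind
the original controller are not public, so equivalence is architectural,
not numerical. At run time the network output passes a safeguard stage —
multiplier `clamp(1 + gain·e, lo, hi)`, then dose bounds — and a
first-order command smoother (α = 0.3 per tick). The smoother is a
deliberate stability measure: a static (e, ė)→dose policy at this loop
gain bang-bangs against the plant's 15 s lag at 10 s ticks. Aggressive and
conservative profiles share the network and differ only in safeguard
gain/bounds.

**ADRC.** Tracking differentiator: critically damped second-order tracker
implemented by its exact discretization (stable for any speed; collapses
onto the setpoint in one tick in the fast limit). ESO: canonical
third-order observer for `ÿ = f + b·u` with bandwidth gains
`(3ω, 3ω², ω³)`; the control input enters the rate (z2) equation — the
placement that makes `z3 → −b·u` at steady state and gives the law
`u = (kp(v1 − z1) − kd·z2 − z3)/b` its integral action. `kp` scales up
linearly with |v1 − z1| (saturating at 2× by 20 mmHg). Trend-aware
limiting: no rate increases while the estimated MAP slope exceeds
+4 mmHg/min; decreases halved below −4 mmHg/min; plus the per-tick slew
limit.

**PFC.** Rolling-mean smoothing (10/5 samples), relative error
`e = (target − m)/target`, least-squares gradient over the last five
samples, and a tracked gradient minimum replaced only by values
≤ 1.05×min. When the gradient stays above `θ·grad_min` for five
consecutive samples — the sign that the current dose's effect has
saturated — and MAP is more than 1 % *below* target, the dose steps up by
the fixed increment (0.25/0.5 mL/min) and the tracker resets. The
below-target condition is deliberate: a pure "not within 1 %" deadband
keeps escalating doses after the target is crossed. Only the ramping phase
is implemented; weaning (dose decreases) is out of scope.

## Metrics

Performance error is `PE = 100·(m − target)/target`. Areas integrate
fractional PE over minutes with a left Riemann sum (a plateau of N samples
contributes exactly height × N·dt). `area_below` counts only times after
the target was first reached and is reported ≤ 0. Rise time (first
crossing of 90 % of target) interpolates linearly between ticks.
`mdape_ss` restricts MDAPE to after the rise time, falling back to the
final third of the run when 90 % is never reached so that failed runs
still produce a value. Divergence is the least-squares slope of |PE| vs
time (hours) over the final 10 % of the run; its sign is kept in the
metric set and the absolute value is taken during normalization.
`var_inf_rate` is the median over sliding 2-min windows of the
within-window population SD of the infusion rate — the window statistic is
ambiguous in the source description, so the choice is isolated behind one
function. `max_rate_change` is the max |slope| of the 3-min moving-average
rate.

## Scoring

Per scenario, each metric is normalized by the median of its absolute
values across the ten configurations (scale-invariant per metric; robust
to outlier controllers). If a metric's median is zero — e.g. AreaAbove in
panels where most controllers never overshoot — zeros map to 0 and
non-zeros are normalized by the smallest non-zero |value| (logged). The
two-metric overshoot and undershoot terms are divided by 3, not the 2 that
the term definitions suggest: every cross-checkable published term value
is consistent only with divisor 3, so 3 is the default and 2 is available
behind `divisor_two_metric`. Ranking ties break lexicographically by
configuration id. The sensitivity analysis sets each term weight to
0.5×/1×/2× (others at 1×) and re-ranks.

The packaged benchmark fixtures carry one caveat (noted in the CSV): the
45 and 55 mmHg stable-term reference cells cannot be derived from the
rounded printed panels under any convention tested — they were evidently
computed from unrounded internal data — and are excluded from
reproduction checks, as are infusion cells dominated by metric values
printed with one or two significant digits.

## Scenarios and problem sizes

The standard battery is 10 configurations × 3 scenarios (starting MAP 35,
45, 55 mmHg; target 65 mmHg; 10 mL/min hemorrhage; 30 min; controller
tick 10 s; plant step 0.25 s), one run per cell, noise off — ~7 200 plant
steps and 180 controller ticks per run, about one second of wall time for
the full battery. A `--replicates` option re-runs cells with offset seeds
and averages metrics before scoring.

## What the simulations do and do not show

The virtual patient reproduces the *shape* of vasopressor response
dynamics, not any particular animal: its parameters are calibrated to the
dosing ladder and plausible equilibria, the hemorrhage is a constant
drift (no volume–pressure curve, no baroreflex, no heart-rate or cardiac
output effects), and noise is disabled in the standard battery.
Controller comparisons on this plant are therefore qualitative: rate
limits, step quantization, rise-time orderings between tunings, and the
relative standing of architectures are meaningful; absolute metric values
are not predictions of hardware or in vivo performance. The published
benchmark's trace-level results additionally depend on undisclosed tuned
gains, so the package's simulation checks are property-based (orderings,
bounds, quantization) while numerical reproduction targets the scoring
pipeline, which is fully determined by the printed tables.

## Numerical choices and degenerate inputs

Traces must be uniformly sampled and strictly increasing in time;
anything else is a validation error, not resampled. Divergence requires
at least 3 tail samples (NaN sentinel otherwise). The Sugeno inference
returns Maintain (0) if no rule fires. Gbell strengths are strictly
positive, so AN-FIS normalization cannot divide by zero (asserted). All
stochastic paths take explicit integer seeds; identical seeds give
bit-identical traces and trained models.
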