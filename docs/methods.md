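# Methods

## The circulation models

`cardiofit` simulates two zero-dimensional (lumped-parameter) models of the
left ventricle and systemic circulation.

**Closed loop.** Three compliant compartments — left ventricle, systemic
arteries, systemic veins — exchange a fixed total stressed blood volume
`V_tot`. The states are the stressed volumes `(V_lv, V_ao, V_sv)`;
compartment pressures are `P_lv = E(t)·V_lv`, `P_ao = V_ao/C_ao`,
`P_sv = V_sv/C_sv`. Flows are pressure differences over resistances
(`Z_ao` aortic characteristic impedance, `R_sys` total peripheral
resistance, `R_mv` mitral valve resistance); the aortic and mitral valves
are ideal diodes (flow clamped at zero under reverse bias — no backflow, no
inertance, no regurgitation). Volume is conserved by construction: the
three state derivatives sum to zero.

**Open loop.** A three-element Windkessel (`Z_ao`, `C_ao`, `R_sys`
referenced to zero pressure) is driven by the same elastance ventricle and
filled from a constant venous source pressure `P_fill` (default 7.5 mmHg,
configurable). The states are `(V_lv, P_ao)`. Because there is no venous
compartment, the mean-venous-pressure term of the fitting cost does not
apply to this variant.

**Elastance.** The ventricular elastance rises from `E_min` to `E_max` as
`sin²(π t/(2 t_peak))` and relaxes as
`cos²(π (t−t_peak)/(2 (T_rel−t_peak)))` with `T_rel = min(1.5 t_peak, T)`,
then stays at `E_min` for the rest of the cycle. Cycle time zero is the
onset of ventricular activation. This waveform was chosen because it
satisfies the needed constraints (0 at cycle start and end, 1 at `t_peak`,
continuous) with only two interpretable timing parameters; it is a
documented stand-in, not a fit to measured elastance curves, and the
activation is pluggable if an alternative (e.g. double-Hill) is preferred.

**Solver.** Fixed-step classical RK4 with `dt = 1 ms`, integrated cycle by
cycle until the maximum per-sample relative change of all states between
consecutive cycles falls below `1e-4` (capped at 50 cycles; non-convergence
is flagged on the result, never silently ignored). The final cycle is
resampled by linear interpolation to `N = 100` output points. Halving the
step changes stroke volume and systolic pressure by well under 0.1%. The
inner loops are numba-compiled; during optimization each simulation is
warm-started from the previous steady state, which typically cuts the
transient to 2–5 cycles.

**Typical parameter values.** The defaults in
`personalization.TYPICAL_PARAMETERS` (and the `_OPEN` variant) were tuned
once so that each model reproduces the hemodynamics of a middle-aged
pre-hypertensive adult — SBP ≈ 138, DBP ≈ 87 mmHg, SV ≈ 85 mL, heart period
0.9 s, and for the closed loop a mean venous pressure ≈ 6 mmHg. They serve
as bound centers for optimization and as population means for the synthetic
cohort.

## Personalization

The cost for one participant-day sums squared per-sample pressure and flow
waveform residuals (scaled by `K_p = 100 mmHg`, `K_q = 500 mL/s`) and adds
heavily weighted summary residuals — systolic and diastolic brachial
pressure, stroke volume, and (closed loop) a soft constraint pulling the
mean venous pressure toward 6 mmHg with weight 1/9 — all multiplied by
`7.5²N²/40²`, with `N` the measurement's sample count. The `K` constants
are order-of-magnitude reference levels and are configurable; simulations
that fail to converge or eject no volume return a large penalty (1e12) so
the optimizer can continue past infeasible regions.

Estimation runs an ensemble of bounded local optimizations: `n_starts = 20`
starting points drawn uniformly within bounds (default 0.5–2× the typical
value per parameter; the heart period `T` is always fixed from the
measurement), each minimized with Powell's method on parameters rescaled to
the unit cube (`xtol = ftol = 1e-6`, 2000 evaluations per round, restarted
from its own endpoint up to twice while the cost still improves ≥ 0.1% —
restarting with a fresh direction set markedly helps Powell in ≥ 8
dimensions). Members whose final cost exceeds 2× the best converged cost
are filtered out; the kept members are averaged per parameter and their SD
is reported as the method spread. Everything is deterministic given the
seed.

Estimates are reported both raw and BSA-indexed (`BSA =
sqrt(height·weight/3600)` m²; all mechanical parameters divided by BSA,
timing parameters untouched).

## Conventional estimates

The model-free comparison estimators are `R_sys ≈ MAP/CO`, `C_ao ≈ SV/PP`
and `E_max ≈ P_brachial,sys/ESV` (ESPVR volume intercept neglected, hence
load dependent). MAP is the trapezoidal time average of the pressure
waveform after affine calibration of its extrema to the brachial
systolic/diastolic values; PP is brachial pulse pressure. Note `SV/PP` is
a biased estimator of Windkessel compliance — tests assert order of
magnitude, not equality — while `MAP/CO` recovers the open-loop `R_sys`
exactly at steady state because the terminal pressure is the zero
reference.

## Synthetic cohort

The generator emulates a three-measurement-day longitudinal trial of a
middle-aged pre-hypertensive cohort (n = 25-scale): covariates are drawn
from the published population statistics (height 174.3 ± 8.9 cm, weight
85.9 ± 14.2 kg, age 55.9 ± 3.9 y, VO2max 36.4 ± 6.8 mL/kg/min, 13/25
male). Ground-truth parameters decompose per participant *i* and day *j*
as

    θ_ij = μ · (1 + α_i + effect_j + ε_ij)

with personal deviation α_i (fractional SD 0.10 for R_sys, C_ao, E_max),
day-to-day error ε_ij (fractional SD 0.04), and an intervention effect
ramped linearly from day 1 to day 3 (defaults −5% R_sys, +5% C_ao, +5%
E_max — plausible responses to a 12-week exercise intervention; set to
zero for null cohorts). Optional morning-after-exercise-test days add a
transient offset (default −5% R_sys). Multipliers are truncated to
[0.4, 2.5] to keep parameters physiological; at the default SDs the
truncation is essentially never active, so the closed-form
regression-to-the-mean algebra still applies.

Measurements are forward simulations corrupted with noise at documented
uncertainty magnitudes: ABPM-averaged brachial pressures 0.7%, stroke
volume 20%, VO2max 2.9%, age 1.8%, height 0.6%, weight 0.1%
(multiplicative, truncated/resampled so records stay valid), plus
per-sample waveform noise (1 mmHg, 5 mL/s). The measured ESV is the
minimum simulated stressed LV volume plus a 15 mL unstressed-volume offset.
The measurement-site model is a deliberate caricature: the carotid trace is
the aortic wave mildly smoothed (3-sample periodic moving average), the
finger trace is smoothed more strongly (7 samples) with its systolic peak
amplified 10%, and both are recalibrated to the noisy brachial values.

What passing tests on this cohort do **not** show: fidelity to real
finger-to-aortic transfer dynamics, beat-to-beat variability, device
artifacts, or any physiological coupling between fitness covariates and
mechanical parameters (covariates are independent of parameters unless
configured). Recovery results are an inverse-crime bound — data generated
and fitted by the same model — and therefore measure estimator quality, not
model adequacy for real waveforms.

## Change and correlation analysis

Changes Δ_{i,j} are signed differences between measurement days, computed
pairwise-complete (missing days drop pairs; nothing is imputed), satisfying
Δ_{1,3} = Δ_{1,2} + Δ_{2,3} exactly. Summary tables pool deltas across
participants and the three core day pairs; parenthetical SDs are population
SDs (ddof 0). "All" correlation rows pool every core day pair. Pearson r
is computed from first principles with the two-sided p value from the t
transform (n−2 df) and a 95% CI from the Fisher z-transform; the
implementation is cross-checked against brute-force covariance arithmetic
and scipy.

## Regression analyses

Under the null variance decomposition θ_ij = μ + α_i + ε_ij, the two
regression-to-the-mean checks have closed-form slopes: regressing the
day-3 value on the deviation of the personal day-1/2 average from the
population mean (over all participant-days) gives slope
σ_α²/(σ_α² + σ_ε²/2) > 0; regressing Δ_{1,3} on the day-1 deviation gives
slope −σ_ε²/(σ_α² + σ_ε²). The tests verify the fitted OLS slopes against
these expressions within Monte-Carlo error.

The covariate regressions come in four fixed configurations: A (age, sex,
BMI), B (+SV), C (+VO2max), D (both). The alternative labeling that swaps
B and C is accepted via the `labeling` argument. The change models are OLS
of the standardized day-1→3 parameter change on age, sex and the change
covariates (ΔBMI, ΔSV, ΔVO2max), with both the dependent and the regressors
Z-scored (population SD) so coefficients are comparable; adjusted r² is
reported exactly as computed and may be negative. The longitudinal models
are random-intercept linear mixed models (REML, statsmodels MixedLM;
personal deviations enter the intercept only) of the Z-scored per-day
parameter on grand-mean-centered regressors; reported quantities are the
fixed-effect coefficients with p < 0.05 flags, the residual ("unexplained")
variance, the random-intercept variance, and the grouping structure. Sex
is coded 0/1 (female = 0) before transformation; the coding affects only
the sign of its coefficient.

## Pipeline and determinism

A single top-level seed drives everything: the cohort generator fans it out
via `numpy.random.SeedSequence.spawn` per participant/day/measurement, and
per-fit optimization seeds come from a generator seeded with `seed + 1` in
a fixed iteration order. Two runs of the same configuration produce
byte-identical tables. Every output records a hash of the scientific
configuration (output paths excluded). Stage failures carry the stage name
and participant context; partially written outputs are preserved.

## Problem sizes and numerical choices

The validation experiments run at desk scale, chosen as the smallest sizes
at which each property is statistically decisive: parameter recovery uses
10 noise-free participants × 20 ensemble starts per model variant;
the change-correlation study uses 30 participants × 3 days with 2% method
noise against 8% day-to-day truth variation (the single-day estimation
variability of the method is well below day-to-day change); the RTM null
study uses 500 participants; covariate LLN checks use 2000 draws. Degenerate
inputs are rejected loudly: constant traces cannot be calibrated, zero-SD
columns cannot be Z-scored, rank-deficient design matrices name their
collinear columns.

## Known limitations

- No atria, right heart, pulmonary circulation, valve inertance or wave
  propagation — pressures at brachial, finger, carotid and aortic sites are
  treated as interchangeable up to the modality distortion model.
- `E_max` from the closed/open loop is identifiable here because the
  synthetic flow waveform is noise-free or mildly noisy; with heavily
  distorted waveforms the ensemble spread widens, which is visible in the
  reported per-parameter spread.
- The ensemble filter (cost ≤ 2× best) is a pragmatic rule; with a
  near-zero best cost it effectively keeps only fully converged members.
- Mixed-model variance components at 0 sit on the boundary of the parameter
  space; statsmodels emits a convergence warning there, which is expected
  for null group variance.
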