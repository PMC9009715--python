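# Methods

## Model

The package estimates whole-body metabolic energy expenditure from joint
kinetics in "joint space": no muscle states, only the moments τᵢ(t) and
angular velocities q̇ᵢ(t) of n = 6 lower-extremity degrees of freedom
(bilateral hip flexion, knee flexion, ankle dorsiflexion), each resampled
to 100 uniformly spaced points over one averaged gait cycle. The
instantaneous rate decomposes as work + heat + basal:

    Ė_met(t) = Σᵢ τᵢq̇ᵢ + Σᵢ hᵢᵃᵐ|τᵢ| + Σᵢ hᵢˢˡ|τᵢq̇ᵢ| + Ė₀

The hᵃᵐ family (W per N·m) prices torque maintenance and co-contraction;
the dimensionless hˢˡ family prices mechanical power throughput. Both are
affine in the subject's mass, age, and height, times a strength multiplier
`1 + w₄·(τ_knee^max/τ̃_knee^max)·τ̃ᵢ^max`. Assumptions worth stating:

- the six sagittal DOFs proxy whole-body energetics (trunk/arm musculature
  is absorbed into the calibrated coefficients);
- all DOFs are summed jointly — no per-leg averaging;
- the cycle mean of the 100 samples is the average rate (equivalent to
  trapezoidal integration of a periodic signal; no integration rule beyond
  that is imposed);
- the basal term uses the Harris–Benedict equations (kcal/day converted to
  watts) and is included by default so modelled costs are gross, directly
  comparable to calorimetry; an `include_basal` flag removes it.

Per-distance cost is E^M = mean rate / (mass · speed), in J·kg⁻¹·m⁻¹.

### Parameters and defaults

| parameter | units | default | why |
|---|---|---|---|
| w vector (10) | mixed | fitted / shipped fixtures | design variables of the calibration |
| τ_knee^max | N·m | 212.4 (M) / 107.6 (F) when unmeasured | population averages by sex |
| τ̃_knee^max, τ̃ᵢ^max | N·m | 160.0, uniform | midpoint of the sex-specific knee averages; the true population values are not published here, and the calibrated w₄ weights absorb this scale. Configurable via `NormativeTorques`; treat cross-study comparisons of w₄ with caution. |
| E^max fraction | – | 1.10 (level, uphill, downhill@0.8); 1.15 (downhill@1.3) | upper bound on modelled cost as a multiple of measured cost |

Negative heat coefficients are never clipped at evaluation time: an
infeasible parameter set must surface through the constraint checker, not
be silently repaired.

## Calibration

One parameter set per walking condition minimizes f(w) = Σ(E^Ex − E^M)²/N
subject to: (7–8) non-negative affine coefficient terms for every training
subject; (9–10) non-negative strength multipliers per DOF; (11) the
no-recharge bound τᵢq̇ᵢ + hᵢᵃᵐ|τᵢ| + hᵢˢˡ|τᵢq̇ᵢ| ≥ 0 at every sample of
every training trial (enforced on the 100-point grid, where the data are
defined); (12) 0 ≤ E^M ≤ E^max per trial.

Numerical design:

- **Scaling.** The ten weights naturally span ~5 orders of magnitude, so
  the solver works in scaled coordinates (`DEFAULT_SCALE`), making swarm
  steps and finite-difference gradients meaningful in every dimension.
- **Stage 1 — particle swarm.** 100 particles, constriction coefficients
  (χ = 0.7298, c₁ = c₂ = 1.496), no bounds; initial box ±2 scaled units
  with the zero vector always included. Constraints enter as an additive
  quadratic penalty with weight 10³·(mean E^Ex)². Termination: relative
  best-objective improvement < 10⁻⁶ for 20 consecutive iterations, or 400
  iterations.
- **Stage 2 — local refinement.** SLSQP (gradient-based, honors nonlinear
  inequality constraints, ftol 10⁻⁶) started from the top 3 distinct swarm
  personal bests; best penalized result wins. Refinement never worsens the
  stage trace — the swarm point is kept if it would.
- **Stage 3 — minimum-norm polish.** The model is over-parameterized (10
  weights, typically 16 trials), so near-optimal weight vectors abound and
  extrapolate very differently to new subjects. The objective, a mean of N
  squared residuals, carries a relative sampling error of about √(2/N);
  differences inside that band (plus an absolute floor of (10⁻³·mean
  E^Ex)², below measurement precision) are statistically
  indistinguishable. Among such points the solver takes the one of
  smallest scaled norm (the one-standard-error rule familiar from
  regularized model selection). The polish is accepted only if it is
  constraint-feasible and keeps the stage trace monotone.
- Feasibility is declared when every margin ≥ −10⁻⁸; otherwise the result
  is returned flagged infeasible with its constraint report, never
  silently as feasible. A single integer seed fixes the swarm and is
  recorded in the result.

Training uses all training-subject trials of a condition (8 subjects × 2
speeds = 16; the split is always by subject so both speeds of a subject
stay on one side).

## Synthetic data

The generator emulates the study conditions end to end: 12 subjects drawn
from sex-stratified truncated normals (males 74.72 ± 14.73 kg, 1.80 ±
0.08 m, 25.0 ± 5.9 y; females 64.30 ± 9.32 kg, 1.68 ± 0.08 m, 22.3 ±
4.0 y), sexes alternating so leading splits stay balanced; six conditions
per subject (0.8 and 1.3 m·s⁻¹ × grades −8/0/+8 %); per-DOF torque and
velocity waveforms as random-phase truncated Fourier series (3 harmonics)
with amplitudes (hip 50, knee 45, ankle 70 N·m at 70 kg; 2.0/3.5/2.5
rad·s⁻¹ at 1.3 m·s⁻¹) scaling linearly with mass and speed and by
(1 + 0.04·grade) on torques, chosen once to land measured costs in the
3–6 J·kg⁻¹·m⁻¹ range of graded treadmill walking with the expected
uphill > level > downhill ordering. Measured costs are the ground-truth
model cost times (1 + ε), ε ~ N(0, σ) truncated to keep costs positive;
σ defaults to 0.05 (typical indirect-calorimetry repeatability) and the
recovery experiments use 0.02. The ground-truth parameter set is strictly
feasible by construction (hˢˡ > 1 makes the no-recharge bound hold
algebraically). Generation is a pure function of one seed at every level.

These waveforms are statistical stand-ins, not physiological gait curves:
they reproduce the data's shape, scale, and condition trends, not joint
coordination, double-support timing, or torque–velocity coupling. Passing
tests therefore demonstrate the correctness and stability of the
machinery — model algebra, constrained solver, statistics, file formats —
not the biomechanical fidelity of any fitted coefficient values; fits to
real gait data remain the scientific arbiter, and the printed RMSEs of the
original study are only reproducible with its external dataset.

## Statistics

RMSE; Bland–Altman bias with 95 % limits of agreement (bias ± 1.96 ×
sample SD of the differences, estimated − measured); independent-samples t
in pooled (df = n₁ + n₂ − 2) and Welch (Welch–Satterthwaite df) forms.
The t-test accepts group summaries (n, mean, sample SD) as first-class
inputs because published cohorts are often reported only as sex strata;
pooling combines within-stratum sums of squares with between-stratum mean
shifts. Sample SD (n − 1) is used everywhere. `group_screen` delegates
Shapiro–Wilk and Levene to scipy and recommends Welch when Levene rejects
at p < 0.05. Degenerate inputs: zero variance in both groups with equal
means defines t = 0; groups of n < 3 skip the normality test with a
warning.

## Empirical comparators

Pandolf: Ṁ = 1.5·M + 2.0·(M+L)·(L/M)² + η·(M+L)·(1.5·V² + 0.35·V·G) W,
divided by M·V for cost; valid for G ≥ 0 — negative grades require an
explicitly supplied downhill correction, never a silent extrapolation.
Looney (level): Ṁ/M = 1.44 + 1.94·S^0.43 + 0.24·S⁴ W·kg⁻¹. The Ludlow &
Weyand equation, Looney grade terms, and the Santee downhill correction
are accepted as user-supplied coefficient sets/callables rather than
hard-coded, because their exact constants are not packaged here.

## Problem sizes and determinism

The shipped tests and the acceptance script run the recovery experiment at
the study's own scale (12 subjects, 16 training trials, 100-particle
swarm), completing in tens of seconds per calibration. All randomness
(cohort, waveforms, noise, swarm) descends from explicit integer seeds;
pipeline output files are byte-identical across reruns with fixed seed and
config.

## Known limitations

- Synthetic waveforms are not biomechanically realistic (above).
- The normative-torque defaults are stand-ins; only ratios against them
  are identified, jointly with the w₄ weights.
- The calibration is per condition; no single parameter set is fitted
  across grades.
- The no-recharge constraint is enforced only at the sampled grid points
  of the training trials.
- The Bland–Altman limits use the large-sample 1.96 multiplier without a
  small-sample correction, matching common practice.
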