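# Methods

This note documents the models, conventions and numerical choices behind
`primadapt`, in the spirit of a model-description appendix.

## Reach kinematics and field laws

Reaches are 10 cm point-to-point movements along the sagittal axis,
represented by scalar position/velocity traces; only the lateral force
channel is modelled because only it is analyzed. The kinematic stand-in is
the minimum-jerk profile x(τ) = D(10τ³ − 15τ⁴ + 6τ⁵), τ = t/T — the
canonical bell-shaped speed profile — with the duration set by the
requested peak speed through T = 1.875·D/v_peak. Peak speeds are drawn
from the rewarded 0.25–0.35 m/s band, so every synthetic trial passes the
0.2–0.4 m/s analysis filter.

The time grid spans exactly [0, T] with an even number of steps whose size
is as close as possible to the nominal 1 ms sample (1 kHz acquisition).
This places the peak-velocity sample exactly at τ = 1/2 and makes the
boundary invariants (endpoint position, zero boundary velocities, realized
peak speed) hold to machine precision; the cost is a realized step that
deviates from 1 ms by ≲0.2 %. All window-based analysis resamples onto a
canonical grid, so heterogeneous trial grids are harmless.

Field law: f_lat = sign·(c_K·K·x + c_B·B·ẋ) with K = 45 N/m and
B = 15 N·s/m — the unit assignment that is dimensionally consistent and
gives pure position and pure velocity fields equal 4.5 N peak force on the
criterion reach. Couplings: pFF (1, 0), vFF (0, 1), ucFF (0.71, 0.71),
pcFF (0.85, 0.53), vcFF (0.53, 0.85). The error-clamp servo (6 kN/m
spring, 150 N·s/m damper) is recorded as metadata only; clamp trials are
modelled as perfectly straight reaches.

Sign convention: recorded error-clamp force is multiplied by the subject's
counterbalanced field sign before analysis, so compensation of the trained
field is always positive. The ideal-force regressor is built from the
trial's own windowed kinematics (not a canonical template); the
alternative template convention would only matter if trial kinematics
varied systematically across epochs, which the generator does not produce.

## Trial schedule

The published session counts are internally inconsistent at the margins
(movement totals vs. ratio decompositions); the generator fixes one
self-consistent reading and documents it:

- baseline: 372 movements — 360 nulls plus 12 trained-direction
  error-clamp probes inserted additionally in the second half (6 per
  block, never a block's first trained slot);
- adaptation transition: 124 movements — 30 nulls, then field onset with
  trained-direction ratios 3 FF : 2 EC over the first 10 movements and
  5 FF : 1 EC over the remaining 84;
- adaptation: two 96-movement blocks at exactly 5 FF : 1 EC (8 probes per
  block, 16 total);
- decay transition: 26 movements of training (6 trained at 5 FF : 1 EC,
  then 7 at 4 FF : 3 EC);
- decay: 120 consecutive error-clamp trials (60 trained).

Directions strictly alternate (each endpoint is the next start), training
fields are never applied in the untrained 90° direction, and every
untrained reach after field onset is clamped. Ratios are realized exactly
by randomizing probe positions within fixed-size sub-blocks, so the
schedule is pseudo-random only in probe placement and is a pure function
of (field type, seed).

The training index counts trained-direction FF trials from onset; EC
probes inherit the most recent count (they measure, they do not train).
The generated session contains 127 training trials, so the package's
pipelines use the last 10 training trials (118–127) as the late-adaptation
window; the classical trial-number windows (1–15 early, 150–160 late;
decay trials 11–20 and 50–60) are kept as named defaults for data indexed
on a denser convention, and every epoch routine takes the window as a
parameter.

## Primitive model

State update per training trial: y⁺ = diag(α_K, α_B)·y + η(SᵀS)(y* − y),
error taken from the current state. Decay trials apply retention only,
y⁺ = diag(α_K, α_B)·y, with no weight update: the defining property of the
model's decay phenomenology — straight-ray decay whenever α_K = α_B
regardless of Σ, and curvature set solely by the retention ratio — follows
only under this rule.

Ensemble mode samples N primitives from N(0, Σ) and uses the sampled SᵀS
(the matrix is trial-invariant, so sampling error enters as a fixed
perturbation of the learning operator, concentrating as 1/√N). Mean-field
mode replaces SᵀS by N·Σ, a deterministic 2×2 linear recursion with
closed-form asymptote y∞ = (I − A + ηNΣ)⁻¹ηNΣ·y*. N is not separately
identifiable from gain trajectories — only the product η·N·Σ acts — so the
package fixes η = 1.5 × 10⁻⁴ (the conventional value) and N = 2000 by
default, and both generation and fitting share them.

Published parameter sets are shipped as named constants
(`VFF_PFF_SYMMETRIC`, `VFF_PFF_ASYMMETRIC`, `UCFF_PCFF_ASYMMETRIC`,
single-condition and vcFF-simulation sets). Where two printed variants of
the same estimate disagree, the constants carry the primary reported set.

## Force-profile analysis

Signals are linearly resampled onto a ±750 ms, 1 ms grid centered on the
trial's peak velocity, zero outside the recorded reach. Zero-padding
contributes nothing to intercept-free sums, and linear interpolation
commutes with the linear force model, so the zero-noise round trip
(synthesize force from (k, b) → decompose) is exact to machine precision.

Per subject, the mean windowed baseline EC force profile is subtracted
sample-by-sample from all EC forces before regression; regressions are
intercept-free because the baseline step already removes bias. The
adaptation coefficient is Σ(f_s·f_i)/Σ(f_i²); the gain decomposition is
the two-regressor least squares on (pos, vel) rescaled by (45, 15), with
the uncentered R² reported (the appropriate definition for a no-intercept
model). Regressors whose condition number exceeds 1e8 are rejected as
collinear. The optional acceleration regressor (differenced velocity) is
reported separately and never folded into (k, b); on forces generated from
position and velocity it improves R² by well under 0.03.

Note the adaptation coefficient equals the goal-aligned gain of the
decomposition only when the misaligned gain is zero: position and velocity
traces are correlated within a reach, so the simple regression absorbs
leakage from a nonzero misaligned gain that the multiple regression
partials out.

Epoch statistics average within subject first, then across subjects (SEM
across subjects); decay series are normalized by the cross-subject mean of
the first decay trial. Group comparisons use Welch or paired two-tailed
t-tests with optional Bonferroni correction; degenerate zero-variance
inputs are flagged rather than silently returning infinities.

## Fitting

Exponential fits use y(n) = a·e^(−n/τ) + c (fall) or c − a·e^(−n/τ)
(rise), nonlinear least squares with warm starts from the linear (a, c)
subproblem at τ ∈ {2, 5, 10, 20, 40} and τ bounded to (0.1, 500];
numerically constant series short-circuit to a degenerate flag (a = 0, τ
unidentifiable). The bootstrap draws n_subjects subjects with replacement,
averages their series pointwise, refits, and reports the across-replicate
SD of each parameter (500 replicates by default; failed or degenerate
replicates are excluded and counted).

Primitive-model estimation minimizes unweighted summed squared error
between mean-field (k, b) trajectories and observations at their trial
indices, pooled over all supplied conditions with adaptation and decay
weighted equally. Observations may sit at sparse probe indices; the model
is simulated densely and sampled at them. The symmetric variant fits
(α, σ, ρ); the asymmetric variant (α_K, α_B, σ_K, σ_B, ρ) with retention
free in either direction. Optimization is Nelder-Mead from 8
Latin-hypercube starts (seeded), a bound penalty outside α ∈ (0.5, 1],
σ ∈ (0.02, 3), |ρ| ≤ 0.95, and a final polish restart; on noiseless
trajectories the retentions are recovered to ≈1e-6, far inside the 0.005
reporting precision.

## Synthetic cohorts

Defaults mirror the study conditions: 14 subjects per group, one field
type each, field sign counterbalanced by subject parity, probe placements
re-randomized per subject. Noise has three components chosen so that
cross-subject SEMs of epoch-mean gains land in the observed 0.02–0.05
range: per-trial gain noise SD 0.05, additive force noise SD 0.10 N, and a
multiplicative between-subject asymptote factor with SD 0.10 applied to
the goal. Baseline EC trials carry pure force noise (zero gains), so the
post-subtraction baseline is mean-zero. Untrained-direction trials carry
no force data but remain in the schedule for index fidelity.

What the generator does *not* emulate: online feedback corrections inside
the clamp, trial rejections/timeouts, temporally correlated motor noise,
fatigue, savings, or generalization across directions. Passing tests
therefore certify the estimation machinery (windowing, regression,
normalization, bootstrap, model fitting) under the model's own data-
generating process, not the fidelity of the primitive model to real limbs.

## Problem sizes and determinism

Unit and pipeline tests run cohorts at 250–500 Hz sampling and 2–14
subjects; the acceptance script and bootstrap demonstrations use the full
500-replicate bootstrap and 160 + 60-trial mean-field trajectories.
Ensemble/mean-field agreement is checked at N = 10⁴ primitives over 20
seeds (max per-trial deviation of the seed-averaged trajectory < 2 % of
the goal norm). Every stochastic component takes an explicit seed and
cohort generation is byte-reproducible in (spec, seed).

## Known limitations

- The schedule reading resolves published count inconsistencies in favor
  of exact headline counts (360 baseline nulls, 124/146-movement
  transitions, 16 adaptation probes, 120/60 decay clamps); per-block null
  splits differ by a few trials from the prose description.
- Behavioral asymptotes and time constants produced by the shipped
  parameter sets describe the model, not any particular dataset; no human
  data are included or reproduced.
- The exponential amplitude parameterization ("rate and offset") is one of
  several equivalent conventions; amplitudes are reported as fitted.
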