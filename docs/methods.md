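# Methods

## Model summary

A reach is planned in two stages.  First, for a reference duration of 1.0 s,
a minimum commanded-torque-change trajectory is computed for the two-link
planar arm; this *time-normalized* movement fixes two shape constants: the
smoothness constant `a` (integrated squared torque-change per unit normalized
time) and, per motor-noise draw, the endpoint-error constant γ.  Second, the
movement duration D is chosen to minimize

    C(D) = a/D⁵ + λ (W★ − γ/D)²,   D ∈ [0.40, 1.50] s,

and the normalized movement is rescaled to D★ (θ(t) = θ̃(t/D★)).  Because γ
is random, D★ has a distribution; the pipeline reports per-draw values and
uses the median as the headline duration.

## Arm model

Standard closed forms for the inertia matrix, Coriolis and centrifugal
coefficients of a two-link chain are used, with link inertias specified about
the joints and a constant symmetric positive-definite joint-viscosity matrix
B.  There is no gravity term (horizontal, air-sled-supported movements).
Correctness is pinned by mechanics identities rather than transcription: the
energy-rate test (τ·θ̇ equals the kinetic-energy derivative when B = 0) and
the exact duration-rescaling law τ(Ds) = τ̃(s)/D² at B = 0.  Forward dynamics
integrates with fixed-step RK4 at the profile's own sampling (500 Hz at
D = 1 s); inverse and forward dynamics round-trip to ~1e-5 rad on smooth
movements.

Subject parameters (link geometry, masses, inertias, per-direction viscosity
blocks, noise coefficients k₁/k₂ and calibrated λ weights) are packaged as
plain CSV tables for six subjects, A–F.

## Trajectory planner

The published neural-network trajectory generator is treated as a black-box
minimizer of the torque-change cost and replaced by direct trajectory
optimization: each joint angle is the minimum-jerk quintic between its
boundary values plus a polynomial correction under the envelope s³(1−s)³
(Chebyshev-weighted, 8 coefficients per joint by default).  The envelope
vanishes to second order at both ends, so position, velocity and acceleration
boundary conditions hold exactly by construction.  The objective is the
discretized torque-change cost on a 100-point s-grid with torques from
inverse dynamics; L-BFGS-B with numeric gradients minimizes it from the
quintic initialization (the minimum-jerk basin, matching the near-straight
bell-shaped solutions this model is known for).  Output trajectories are
evaluated analytically from the polynomial representation at 500 Hz.

Two oracle families validate the planner: with constant inertia and
negligible viscosity the exact minimizer is the per-joint quintic (matched to
1e-3 rad), and with B = 0 the optimal cost scales exactly as D⁻⁵ (matched to
2%).

## Noise model and conventions

Motor noise is signal-dependent: the torque perturbation at joint i has
standard deviation kᵢ|τᵢ|, white across samples.  Linearizing the endpoint
response through the viscosity (δẋ = J B⁻¹ δτ) gives the per-joint integrals
α and the duration-free constant γ with Ŵ = γ/D.

Three conventions matter and are frozen deliberately:

- **Grid.**  The stochastic integrals are discretized on a fixed 501-sample
  s-grid (500 intervals; trapezoid weights) with i.i.d. standard-normal z per
  sample, the literal reading of the printed integrals.  Under grid
  refinement the variance of such a sum scales with Δs, so the k coefficients
  are meaningful only relative to this grid; the Monte-Carlo scatter
  simulator therefore also uses a fixed 501-sample time grid per movement
  (dt = D/500).  Both routes then obey the same 1/D endpoint law.  A
  per-absolute-time-step (true white-noise) convention would instead give
  Ŵ ∝ D^(−3/2).
- **Commanded torque.**  The noise rides on the planned command
  τ̃(s)/D², not on the exact inverse-dynamics torque of the rescaled
  movement.  The two differ by the viscous-scaling approximation (1/D vs
  μ/D²), which errs by up to ±40% at the band edges; with the commanded
  torque the linearized γ/D prediction matches the full nonlinear Monte-Carlo
  scatter within ~15% in median across the band.  `simulate_endpoint_scatter`
  accepts any torque profile, so the unapproximated variant remains
  available.
- **Settled endpoint.**  The arm's mechanical time constant M/B is ~0.3 s, so
  noise kicks near movement end have not yet become displacements at the last
  sample.  The simulator's default endpoint is the settled one,
  x_end + J B⁻¹ M θ̇_end (linearized free decay), matching the assumption of
  the α integrals; `settle="none"` gives the raw terminal position.

`[B⁻¹]ᵢ` is the i-th column of B⁻¹: a torque perturbation at joint i maps
through the viscosity to a joint-velocity perturbation, which the Jacobian
carries to the hand.

### Noise-parameter estimation

(k₁, k₂) are estimated by grid search ([0, 2] in steps of 0.01) matching the
simulated endpoint covariance to a reference scatter in Frobenius distance —
the operational form of requiring overlapping 95% confidence ellipses, which
the source procedure does not operationalize further.  To make the search
cheap and smooth, the candidate scatter is assembled by linear superposition
of two probe simulations (noise at one joint at a time through the full
forward dynamics); the endpoint response is linear in noise amplitude to
first order at these magnitudes (mm-scale deviations on a 150 mm reach).
Self-recovery of the packaged coefficients from a 1000-draw reference lands
within one grid step.

## Duration optimizer

`Rprop` follows the sign-based description: the step η grows by η⁺ = 1.2
while the gradient sign repeats (only while η·η⁺ < η_MAX = 50), shrinks by
η⁻ = 0.5 on a sign flip (only while η·η⁻ > η_MIN = 1e-6), initial
η = 0.01; D moves by −sign(dC/dD)·η, clamped to [0.40, 1.50] s with η reset
on clamping.  η is used as an absolute step length (a multiplier on a raw
gradient of magnitude up to ~1e6 would be meaningless against η_MAX = 50).
Iteration stops when the step falls below 2.5 µs-of-duration or at the
bounds; among visited iterates the one with the smallest gradient magnitude
is returned, so interior optima are stationary to ~η_MIN precision.  The
start point is the band midpoint, 0.95 s; agreement with a 1e-4-resolution
grid search (within 1e-3 s on random models) makes the initialization
immaterial.  The batched implementation used for draw ensembles applies the
identical update rules (tested against the scalar routine).

μ = (∫D⁻³dD)/(∫D⁻⁴dD) over the duration band, the closed-form least-squares
match of 1/D by μ/D²; for [0.40, 1.50] s this is 0.5681.

## Calibration

λ is fitted per direction on a 41-point log grid over [1e5, 1e7] (the spacing
is a package choice; only the range is prescribed), minimizing the MAE
between measured and model duration-table cells at the measured tolerances
{8, 15, 25} mm.  Two conventions make the objective well-posed:

- **Matched statistic.**  Measured cells are means of segmented durations;
  model cells are means over draws.  Mixing mean-measured with median-model
  biases λ low by ~2 grid steps because the D★ distribution is right-skewed.
- **Matched duration convention.**  Segmented durations span the 5%-of-peak
  velocity crossings and are therefore ~12% shorter than planned durations
  (for a quintic speed profile the crossing span is 0.881·D, from
  30s²(1−s)² = 0.05·1.875).  Model cells are converted with the planned
  velocity profile's own crossing fraction by default
  (`model_duration="segmented"`); `"planned"` compares raw D★.

The γ draws are frozen per direction across the grid, so the argmin is
deterministic and recoverable: a synthetic session generated at a known λ
refits to the same grid point.

## Synthetic sessions

The generator replays the full generative model per trial: a γ draw fixes
D★, the normalized plan is rescaled, signal-dependent noise is added to the
trial's torque and integrated through the forward dynamics, and the hand
path is emitted at 500 Hz with 0.3 s of quiescent padding (0.1 mm positional
jitter) on both sides.  Ground truth stores both the planned D★ and its
threshold-convention equivalent.  What the generator does *not* emulate:
trial-to-trial variability of the path shape (every trial shares one planned
path per direction), execution noise during the quiescent phases beyond
jitter, corrective submovements, learning or fatigue effects, and marker
noise spectra of real motion capture.  Passing recovery tests therefore
demonstrate the internal consistency of the analysis chain, not robustness
to every artifact of real recordings.

## Problem sizes and defaults

Planner: 100-point planning grid, 8 basis functions per joint.  Noise draws:
1000 per reported condition (the published convention); 200 per cell during
λ fitting; scatter references 1000 draws.  Synthetic sessions: 200 trials
per condition in recovery studies, 32 in the session CLI (one block per
condition in the original protocol).  These sizes reproduce all orderings
and recoveries stably; they are the package's defaults, not limits.

## Known limitations

- The exact minimum-torque-change optimum depends mildly on the closed-form
  conventions of the arm-dynamics coefficients; numeric equality with other
  implementations' torques is not guaranteed (mechanics invariants, not
  transcription, define correctness here).
- With B ≠ 0 the optimal path is only approximately duration-invariant; the
  normalized-trajectory construction inherits this approximation (it is
  exact at B = 0 and unquantified in the source).
- k coefficients are bound to the 500-interval grid convention; comparing
  them across discretizations requires rescaling by √(Δs ratio).
- The D★ distribution is exponential-like, while measured human durations
  are near-normal; the model's distributional shape is a known mismatch.
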