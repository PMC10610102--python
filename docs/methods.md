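# Methods

## Overview

`gaitsignatures` models treadmill walking as a driven dynamical system and
represents each trial — one person walking at one speed — by a *gait
signature*: the phase-averaged trajectory of the dominant principal
components of a trained recurrent model's internal states. The pipeline has
four stages:

1. **Dynamics model.** A single-hidden-layer LSTM with an affine output map
   is trained to predict the six sagittal joint angles (paretic and
   nonparetic hip/knee/ankle, degrees) one sample ahead, jointly over all
   trials of a cohort.
2. **Internal states.** Driving a trial through the trained network yields a
   per-step state vector of 2U numbers (U activation coefficients H and U
   memory cells C).
3. **Common basis.** One PCA over the concatenated states of all trials
   gives a shared, globally centered, unscaled basis; each trial becomes a
   T'xK score trajectory.
4. **Phase averaging.** A continuous gait phase in [0, 2pi) is estimated
   from the leading score components and the scores are averaged as a
   function of phase with a von Mises kernel, producing the PxK signature.

Signatures are compared by Euclidean distance (flattened column-major),
mapped with classical MDS, and manipulated generatively: single components
can be isolated or swapped between individuals and signatures can be
convexly combined across speeds, with the hybrid cycle decoded back to
kinematics through the model's affine output map.

## The dynamics model

**Architecture.** Input J=6 angles, hidden layer of U LSTM units (default
512; the test and acceptance workloads use 32–64), affine read-out
y = H·Wy + by. The LSTM is the standard formulation (input, forget, cell and
output gates; forget-gate bias initialized at +1; Glorot-uniform weight
init, seeded). Because H = o · tanh(c) with o in (0,1), every activation
coefficient lies strictly inside (−1, 1); the implementation nudges the tanh
away from ±1.0 at float saturation so the bound also holds numerically.

**Lookback mini-batching.** Each trial of length T is tiled by contiguous
blocks of L+1 samples; block inputs are samples [s(L+1), s(L+1)+L) and
targets the same window shifted by one. L must therefore be one less than a
divisor of T (for T=1500: 249, 299, 374, 499, 749, ...). The final segment
of each trial is the validation segment when at least two exist, giving the
2:1 split at L=499 and the 1:1 split at L=749 on 1500-sample trials.

**Stateful training.** All trials advance together (batch dimension =
trials). The hidden state is zero at each trial's start, carried across that
trial's segments within an epoch, and reset between epochs. After every
training segment the mean-squared error (deg^2) is backpropagated through
that segment only (truncated BPTT; the carried entry state is treated as a
constant) and the weights are updated with Adam. Whether weight updates are
applied per segment or per epoch was an open choice; per-segment updating is
the standard stateful recipe and is what we use. Training stops at
`max_epochs` or when the training *and* validation histories each move by
less than `convergence_tol` (default 0.03 deg^2) over a 50-epoch window — a
plateau rule rather than an absolute threshold, so it is meaningful at any
noise floor.

**Normalization.** `normalize=NONE` (default) trains on raw degrees, which
keeps the loss directly interpretable in deg^2. Raw joint angles have
offsets of tens of degrees, which pushes the gates toward saturation and
slows convergence considerably; `normalize=ZSCORE` (used throughout the
test workloads) trains on per-channel z-scores while still recording the
loss history in deg^2 and returning all predictions in degrees.

**Everything is numpy.** Forward pass, backpropagation and Adam are written
out explicitly. This keeps runs deterministic for a fixed seed in
single-threaded mode, makes the internal states first-class objects rather
than framework internals, and keeps the dependency footprint to the
scientific Python stack.

**Generation.** `drive` is the teacher-forced pass (predictions and states
from measured input); `self_drive` primes the hidden state on measured
kinematics and then feeds each predicted posture back as the next input.
Two model-selection scores mirror the short-/long-horizon criteria used for
hyperparameter selection: the short-time score restarts the model from the
reference state at each stride onset and measures the pooled R^2 of the
simulated states over one stride; the long-time score self-drives for a full
trial length and compares phase-averaged state signatures. A simulation that
collapses (no estimable phase) scores −inf.

## Phase estimation

The protophase of a quasi-periodic score trajectory is obtained per channel
as the angle of the analytic signal (Hilbert transform) of the centered
channel; channels are combined by amplitude-weighted circular averaging
after discarding channels whose mean rotation rate differs from the
consensus by more than 30% (these are typically harmonics or
near-zero-amplitude channels). The protophase density is then flattened by
the standard Fourier-series correction

    phi(theta) = theta + sum_n (2/n) Im[ S_n (e^{i n theta} − 1) ],
    S_n = <e^{−i n theta}>,  n = 1..10,

which makes the rotation rate uniform in time for a stationary oscillator.
The S_n are estimated over whole cycles only (a trailing partial cycle
biases them), the Hilbert transform is applied to a mirror-padded copy of
the trace, and the first/last three-quarter cycle of the protophase — where
the analytic signal stalls at the window boundary — is replaced by linear
extrapolation from the adjacent 1.5 cycles. Together these bring the phase
error on noiseless circular limit cycles to ~0.02 rad and on the default
noisy synthetic cohort to ~0.06 rad RMSE against ground truth.
Zero phase is anchored at the circular mean of the phases of the per-cycle
maxima of the first principal component, so phases are comparable across
trials that share a basis. The unwrapped phase is returned nondecreasing;
trajectories traversed backwards are flipped by the sign of the mean angular
velocity. At least two full cycles are required, otherwise the trace is
rejected as insufficiently periodic.

## Von Mises phase averaging

A series x(t) with phases phi_t is averaged onto a uniform P-point grid as

    out(g) = sum_t w_t x(t) / sum_t w_t,   w_t = exp(kappa cos(phi_t − g)).

Weights are evaluated as exp(kappa(cos − 1)) to avoid overflow; the
normalized average is unchanged. Defaults: P = 100 frames per cycle and
kappa = 50, i.e. a kernel angular SD of about 1/sqrt(50) ≈ 0.14 rad (~2% of
the cycle). The kernel attenuates a pure sinusoid by exactly
I1(kappa)/I0(kappa) (≈ 0.990 at kappa = 50), which the tests verify against
the Bessel closed form. A grid point to which no sample contributes weight
(a phase-coverage gap) is reported as an error rather than silently
interpolated.

Gait-event phases (LHS, RTO, RHS, LTO) are summarized per trial as the modal
P-bin of the occurrences' phases, ties broken toward the circular mean.

## Comparison machinery

Distances are Euclidean on flattened PxK signatures; the choice of
vectorization was open and flattening is the simplest faithful one. Maps use
classical (Torgerson) MDS — deterministic, exact for Euclidean
configurations of dimension <= the embedding dimension — rather than a
stress-minimizing variant. Group dispersion is the 95th percentile (linear
order-statistic interpolation) of member distances to the group centroid,
with a drop-one-at-random resampling loop reporting mean ± SE. The
normative band is a pointwise mean ± 1.96·SD envelope; the classifier
harness is a linear SVM under stratified k-fold cross-validation.

## Sculpting and interpolation

All generative manipulations act on phase-averaged score trajectories on a
common grid: components of the recipient's signature are replaced by the
donor's (already phase-aligned by the shared anchor), or one subject's
signatures at surrounding speeds are combined with convex weights; the
result is mapped back to hidden states by inverse PCA (non-kept scores
zeroed, global mean restored) and decoded with the affine output map. Since
the decode is affine, the self-swap and all-swap identities hold bit-exactly
and interpolation is exactly linear in the weights.

A consequence worth stating plainly: with an affine decode and the same
phase machinery on both sides, decoding a convex combination of signatures
equals the same convex combination of the individually decoded cycles. The
signature route to unseen-speed prediction therefore differs from direct
kinematic-cycle interpolation only through the model's reconstruction
fidelity and the rank-K truncation; on the synthetic generator the two
routes give near-identical R^2 (~0.95–0.99), with the kinematic route
usually a hair ahead because it carries no reconstruction error. The
corresponding acceptance check encodes the opposite direction and is
reported failing by design rather than adjusted; see the known-limitations
section.

## The synthetic generator

Each synthetic individual is a Fourier limit cycle per joint:

    theta_j(t) = a0_j + s(v) sum_k A_jk cos(k phi*(t) + psi_jk) + eps(t),

with nonparetic channels evaluated at phi* + pi. Coefficients are drawn from
joint-specific templates (hip/knee/ankle fundamental half-ranges ~17/30/12
deg, harmonic decay 0.3 per order, lognormal individual variation) and
successive individuals are rejected until their amplitude vectors are >= 5%
apart, so identity recovery has a defined ground truth. The amplitude scale
s(v) = 1 + alpha(v − v0) + beta(v − v0)^2 makes speed dependence linear
(beta = 0) or non-monotonic (beta != 0); a0 is speed-independent. Stride
frequency is affine in speed, f(v) = 0.55 + 0.35 v strides/s (~0.9 at
1 m/s), times an individual factor (SD ~4%). Per-stride multiplicative
frequency jitter (CV default 0.02) perturbs the rate while keeping phase
continuous; measurement noise is i.i.d. Gaussian (SD default 0.5 deg).
Events sit at fixed phases (LHS 0%, RTO 12%, RHS 50%, LTO 62% of the
cycle). Defaults: 8 individuals, speeds 0.7/0.9/1.1/1.3 m/s, 15 s at
100 Hz.

What it emulates: individual-specific waveform shape preserved across speed,
speed-dependent amplitude and cadence, stride-period variability, event
labels, the cohort layout of the target protocol. What it does not: transient
or non-stationary gait, asymmetric impairment beyond whatever the random
left/right coefficient differences produce, kinematic constraints between
joints, ground-reaction dynamics. Passing tests on this generator show the
pipeline recovers structure it was designed to recover; they do not certify
performance on real motion capture.

## Problem sizes in tests and acceptance runs

The test and acceptance workloads use deliberately scaled-down models:
64-unit networks, 149-sample lookbacks and 15 s x 100 Hz cohorts of 4–32
trials train in one to three minutes on one CPU, and smaller fixtures (32–48
units, 6–8 s trials) in seconds. These sizes are the package's own test
conditions; the library itself has no special casing for them and accepts
the full-size configuration (512 units, lookback 499).

The acceptance script reports, per run: training/validation loss of the
cohort model; 6-PC explained variance; leave-one-trial-out individual
identification accuracy and silhouette of signatures; phase-recovery RMSE
against generator truth; self-driving period error and range excess from a
dedicated two-individual model; and the signature-vs-kinematic
interpolation comparison over 10 independent cohorts.

## Known limitations

* Long-horizon self-driving from a many-individual cohort model tends to
  entrain toward a cohort-typical cadence rather than each trial's own;
  generative stability is therefore demonstrated on a dedicated
  two-individual model. This mirrors the long-timescale divergence the
  underlying method itself exhibits.
* Under the cycle-domain, affine-decode design adopted here, signature-space
  speed interpolation cannot systematically beat a phase-aligned kinematic
  interpolation baseline (see above); the directional acceptance check for
  that comparison fails on the synthetic generator and is intentionally left
  failing.
* Phase estimation assumes a dominant common rotation across the leading
  components; strongly mixed harmonics or cycle-skipping dynamics would need
  the full Phaser machinery, which this package deliberately replaces with
  the documented protophase-plus-correction procedure.
* The convergence thresholds quoted in deg^2 assume degree-scaled inputs;
  with z-scored training the plateau rule still applies to the deg^2
  history, but the optimizer's effective scale differs.
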