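# Methods

## The grip strength–forearm muscle model

Muscle tissue under contraction behaves viscoelastically. We linearize it
as a Voigt element — a spring and a damper in parallel, the simplest
reduction of Hill-type muscle mechanics — so grip force is an affine
function of the surface deformation it produces:

    F(t) = Σⱼ aⱼ Xⱼ(t) + Σⱼ bⱼ Ẋⱼ(t) + c ,   j = 1 … 12

`X` is the 12-channel deformation signal, `a` the per-channel elastic
gains, `b` the per-channel viscosities, `c` an offset absorbing resting
tone and sensor bias: 25 free parameters per wrist angle. Because grip
mechanics change with wrist posture, one parameter set is fitted per
angle (−90°, 0°, +90°) and the angle classifier selects the active set at
run time.

**Units convention.** `X` is consumed in sensor-voltage units (the
filtered, quantized photoresistor output), not calibrated displacement.
The sensor nonlinearity is never inverted: the fitted `a`, `b` absorb the
local voltage-to-displacement calibration, exactly as a fit on raw
hardware output would. Consequently `a` is in N/V and `b` in N·s/V.

**Estimation.** Ordinary least squares on the design matrix
`[X | Ẋ | 1]` (n × 25), minimizing the residual sum of squares Q, solved
by rank-revealing minimum-norm `lstsq`. No regularization by default (a
ridge option exists); a condition warning is raised when the design is
rank deficient or its condition number exceeds 1e8. Calibration trials
are 1 s ramps at 1000 Hz, so one trial contributes n = 1000 samples; the
reference experiment pools four trials per angle.

**Derivative.** `Ẋ` is estimated by central differences on the
MAF-filtered signal (raw differentiation amplifies quantization noise);
one-sided differences at the series ends. Inside the fitting/estimation
chain the symmetric stencil is widened to half-width 3,
`(x[i+3] − x[i−3])/(6 Δt)`: this attenuates the ADC quantization steps by
a further factor ~3 with zero phase lag, at a truncation error that is
negligible for the signal band (< 10 Hz at 1000 Hz sampling). The same
operator is used when fitting and when predicting, so the model sees a
consistent regressor.

**Filter-delay absorption.** The causal moving-average filter delays the
deformation signal by ~2.5 samples. Because the parameter bank is always
fitted on pipeline-processed signals, the least-squares solution absorbs
this group delay into the `b` coefficients to first order
(v(t−τ) ≈ v(t) − τ v̇(t)); no explicit delay compensation is applied.

## Preprocessing

* **Moving-average filter**, window 6, causal with a growing warm-up
  window: output i is the mean of the last min(i+1, 6) samples, so the
  output has the input's length and no future samples leak.
* **Windowing.** The three Hall channels are cut into non-overlapping
  200 ms windows (200 samples at 1000 Hz) and stitched channel-by-channel
  into one 600-vector. The trailing partial window is dropped;
  mixed-label windows take the majority label, exact ties are discarded.
* **Normalization.** Min-max to [0, 1] over the whole stitched row
  (M = (m − m_min)/(m_max − m_min)); a constant row maps to zeros.
  Row-wise scaling preserves the *relative* levels of the three channels
  within a window — those ratios are the angle signature when the wrist
  is held still. A per-channel-block variant (`scheme="channel"`) is
  available but erases exactly that information for stationary windows
  and is not the default.
* **Split.** Stratified 4:1 train/test partition, seeded.

## The wrist-angle CNN

The stitched window is reshaped to (3 channels × 200 samples) so
convolution runs along time with the three Hall sensors as input
channels. Default architecture: conv(8 filters, kernel 5) → ReLU →
max-pool 2 → conv(16, kernel 5) → ReLU → max-pool 2 → dense softmax over
3 classes; cross-entropy loss, mini-batch SGD (batch 32, learning rate
1e−3, momentum 0.9), 30 epochs. All weights, shuffling and augmentation
derive from one seed, and training is bit-reproducible on a single
thread. The network is implemented in numpy (im2col convolutions with
exact backpropagation); there is no framework dependency.

**Disturbance robustness.** Field disturbances are emulated as
full-scale sample spikes and as loss of 100 consecutive samples in a
window (zero-filled, keeping the length fixed). During training each
window is corrupted with probability 0.25 (one of the two modes at
random). This augmentation is the mechanism behind the classifier's
tolerance to corrupted inputs; the suite checks ≥ 90 % correct
classification of dropout-corrupted windows as a design target.

## The synthetic sensor generator

The generator emulates the statistics the analysis relies on, not the
device physics in detail:

* **Photoresistor curve**: v(d) = v_dark + (v_sat − v_dark)(1 − e^(−d/d_scale)),
  defaults 0.5 V, 4.5 V, 5 mm — a saturating monotone response over the
  0–15 mm characterization range. Each channel additionally carries a
  fixed bias from a ±24 mV spread (electronics tolerance); this also
  prevents all 12 channels from crossing the same ADC code boundary in
  lockstep, which would otherwise produce synchronized derivative spikes
  no real array exhibits.
* **ADC**: clamp to [0, 5] V, round to the nearest multiple of
  5 V/2¹⁰ = 4.88 mV.
* **Hall field**: hᵢ(θ) = baseline + Aᵢ cos(θ − φᵢ) with φ = (−60°, 0°, 60°),
  A ≈ 1.0–1.2 V, baseline 2.5 V — a cosine-of-offset dipole
  approximation; true dipole falloff is irrelevant because only class
  separability at three angles matters. A slow ±2° wrist wobble adds
  realistic within-window variation.
* **Grip trials**: the 12 latent compressions follow a smoothstep ramp to
  per-channel depths of 6.0–10.4 mm over 1 s plus small (0.3 mm)
  per-channel sinusoidal perturbations (2–7 Hz, random phases) that keep
  all 25 parameters identifiable. The latent force is computed *exactly*
  from the true parameter bank on the clean voltages, so a zero-noise
  trial satisfies the model to machine precision before quantization and
  peaks near 33.5 N, inside the 35 N meter range.
* **Noise** (defaults): photoresistor 0.02 V, Hall 0.05 V, force meter
  1.0 N, all Gaussian. At −90° both the deformation and the force noise
  are inflated 1.75×: forceful supination is uncomfortable and degrades
  both signal quality and the force measurement, making −90° the hardest
  posture in the synthetic subjects as it is in practice. (Inflating the
  deformation noise alone measurably changes nothing downstream — the
  1 N meter noise dominates trace RMSE and least-squares attenuation
  absorbs the rest — so the inflation is applied to both.)
* **True parameters**: drawn once from a fixed internal seed,
  independent of the user seed — they are the "subject", not part of the
  experiment's randomness. aⱼ ~ U[0.8, 1.6] rescaled to hit the force
  range, bⱼ ~ U[0.01, 0.04] N·s/V (viscous term small relative to
  elastic, and keeping the noise amplification through Ẋ bounded), c set
  for a 0.5 N resting force.

What the generator does **not** emulate: inter-subject variability,
electrode/sensor drift, fatigue, non-stationary noise, co-contraction,
continuous wrist motion during gripping, and any coupling between grip
force and the Hall channels. Passing tests therefore demonstrate that
the pipeline recovers what the model family can express under realistic
sensor corruption — not that the model family captures real muscle
behavior.

## Reference experiment and problem sizes

The desk-scale experiment (`run_experiment`) uses 333 windows per angle
(999 total, 4:1 split), four 1 s calibration trials and two held-out
trials per angle; it completes in a few seconds on one CPU. All
randomness flows from one top-level seed split into named sub-seeds
(window generation, split, CNN training, trials), so repeated runs are
byte-identical.

## Numerical choices and degenerate inputs

* Constant (zero-variance) fitting designs return the minimum-norm
  solution with a condition warning; the intercept absorbs the target.
* A constant row in min-max normalization maps to zeros.
* Quantization clamps out-of-range voltages rather than erroring — rail
  saturation is the physical behavior.
* The angle (and parameter set) is held constant within each 200 ms
  window; per-sample switching is not attempted. A trailing partial
  window inherits the last classified angle so every sample receives an
  estimate.
* Derivative at the series ends: one-sided second-order differences.

## Known limitations

* The zero-noise end-to-end error is quantization-limited: with a total
  elastic gain of ~14 N/V and a 4.88 mV LSB, per-trial maximum error
  averages ~0.06 N but single trials can reach ~0.12 N.
* Only three discrete wrist angles are supported; no continuous-angle
  parameter interpolation.
* The classifier and parameter bank are subject-specific by
  construction; no cross-subject transfer is attempted.
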