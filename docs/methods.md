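# Methods

## The agent–environment loop

A trial presents a 100 ms white-noise burst from azimuth θ ∈ [−180°, 180°)
(and elevation φ ∈ [−40°, 90°] in 3-D) at 1.4 m.  The agent hears the
source through a direction-dependent acoustic transfer, expressed as
per-ear levels in 24 cochlear channels; it may rotate its head and listen
again (every listen is a fresh noise token).  Azimuth is positive
clockwise (listener's right); all azimuth arithmetic wraps to
[−180°, 180°).

### Cochlear front end

24 cosine-shaped bandpass filters with centre frequencies equally spaced
on the Moore–Glasberg ERB-rate scale between 20 Hz and 20 kHz; half-width
equals the channel spacing, so adjacent filters cross at ≈0.71 gain.
Band levels are RMS levels in dB SPL re 20 µPa; silent bands are floored
at −100 dB (never reached by noise stimuli).  The auditory-nerve transform
is the identity, so the 48-dimensional input to all circuits is the pair
of 24-channel dB vectors (Lη, Rη).

### Synthetic spherical-head model

The packaged, download-free stand-in for a measured HRTF set is defined
directly in the level domain by four direction-dependent gain components
per channel *i*:

* **ILD**: ±A_i·sin(θ)·cos(φ)/2 per ear, with A_i growing linearly along
  the ERB axis up to `ild_max` = 20 dB at 20 kHz (≈10 dB at 2 kHz,
  KEMAR-like magnitudes).  A pure spherical head would make front and back
  indistinguishable from band levels, so two pinna-like cues are added:
* **front/back tilt**: `tilt_db` = 3 dB attenuation of the upper-half ERB
  channels for rear sources, ramped over |θ| ∈ [85°, 95°];
* **elevation droop**: 6 dB × (1 − cos φ) broadband attenuation, giving
  the monaural response a peak at φ = 0;
* **elevation ramp**: ±4 dB × sin(φ) antisymmetric across-band ramp
  (zero mean), making elevation sign decodable from the spectrum.

The monaural (right-ear, across-band mean) response then has a unique peak
near the right ear axis (at ≈85° azimuth, just in front of it because of
the rear tilt), which the peak-seeking procedure exploits.  The model's
waveform path shapes white noise by the interpolated gain curve; the fast
level-domain path returns the nominal band levels plus Gaussian dB jitter
with the chi-square-derived standard deviation of a finite noise token's
RMS estimate (≈2.7 dB in the narrow lowest channels, <0.5 dB at high
frequencies for 100 ms).  A test verifies the two paths agree.

Measured sets load from SOFA/HDF5 (SimpleFreeFieldHRIR); queries are
barycentrically interpolated between the three enclosing measured
positions of the spherical cap.

## Teacher circuits

**Single LSO neuron.**  Mean rate μ(x) = a + b/(1 + e^((c−x)/d)) of the
ILD x at its characteristic frequency (cf), read off the 24-point
magnitude spectrum by linear interpolation on the ERB-rate axis
(extrapolation outside the channel range is refused).  Trial-to-trial
variability is σ(x) = g·|x|^h — the power law is taken of |x| so it is
defined for negative ILDs and symmetric in sidedness.  A normalized rate
r = clip((N(μ, σ²) − a)/b, 0, 1) is sampled and a spike drawn from
Bernoulli(r).  Norm bounds are the theoretical floor/ceiling (a, a + b):
deterministic and data-independent.  A right-side neuron sees x = R − L,
a left-side one L − R.  The default single-neuron teacher uses the table
row nearest 2000 Hz.

**Population.**  32 neurons, cf log-spaced over 20–2200 Hz; r̄ is the mean
normalized member rate, and the plastic readout gives
ρ = logistic(w·r̄ + b) with (w, b) = (10, −5) (≈ identity on [0, 1]);
the spike is Bernoulli(ρ).

**Midline detector.**  Two mirrored populations combined multiplicatively:
r_M = ρ_L·ρ_R / (ρ_L(½)·ρ_R(½)).  The normaliser is the product's
*achievable* peak — the mirrored sides cannot saturate simultaneously, and
with balanced input both readouts sit at r̄ = ½ — so r_M peaks at 1 when
the head faces the source and the detector fires reliably at alignment.
(Normalising by the unreachable joint-saturation value would cap the spike
probability at ≈0.26 and, empirically, starves the reinforcement learner
of reward.)  The detector is broadly tuned (≈0.5 at ±90°) because the
low-cf members carry little ILD.

**Monaural circuit.**  The across-band mean magnitude of one ear.

**Characterisation.**  `estimate_teacher_stats` presents n fresh tokens
per grid angle and records the mean and variance (ddof = 0, hence bounded
by the Bernoulli maximum 0.25) of the binary response.  The bias β is the
0.5 crossing of the mean curve; because the raw empirical curve is noisy,
it is first smoothed with isotonic regression (monotone least squares —
deterministic, no tuning) and the crossing linearly interpolated.  The
variance peaks at the decision boundary; a robust peak location is the
centroid of the near-maximal region.

**Readout plasticity.**  `recalibrate_readout` performs gradient descent
on the binary cross-entropy of ρ against left/right labels, with only
(w, b) plastic.  With fixed magnitude vectors it is deterministic
full-batch descent; given an environment and source angles it re-listens
every step (fresh token, fresh member noise), i.e. SGD over the stimulus
noise, converging toward the boundary between the expected responses.
With two random labels in [−10°, 10°] we draw one angle per side: two
same-side labels (probability ½ otherwise) would leave a left/right
boundary unconstrained near the midline.

**Dynamic-range adaptation.**  After a peripheral disruption the members'
operating range can shift far outside (a, a + b).
`adapt_normalization` re-estimates each member's Norm bounds as the
min/max mean rate reached over an azimuth grid under the current input —
unsupervised firing-rate adaptation, no labels, tuning parameters frozen.
It is applied before readout recalibration in the disruption pipeline.

## Student and optimiser

5 hidden ReLU layers of 128 units, linear output in degrees.  Hidden
weights are He-normal; the output layer is scaled 100× smaller so initial
predictions sit near 0° (the midline).  A fixed affine input stage
(x − 70)/20 — nominal stimulus level and the level-jitter scale, chosen a
priori — standardizes the acoustic input inside the network; raw ~70 dB
inputs make sign-gradient optimization oscillate badly (verified with a
supervised-oracle control).  Adam uses α = 10⁻³, β₁ = 0.9, β₂ = 0.999,
ε = 10⁻⁸, batch 32.  The implementation is plain numpy (flat parameter
buffer, hand-written backprop validated against central finite
differences); the acoustic student uses float32, numeric tests float64.

## Learning procedures

**Surrogate gradient (left/right teacher).**  Per episode: sample
y* ~ U(training range) and a level 70 ± 20 dB; predict ŷ; rotate by ŷ;
re-render at the wrapped residual y* − ŷ; the teacher's spike (right-side
population: spike ⇒ "source right" ⇒ feedback +1) supplies
s ≈ sign(ŷ − y*); the batch gradient is the mean of s·∂ŷ/∂θ — exactly the
L1 gradient when the teacher never errs (tested bit-for-bit).  Reference
schedule: 160k steps, learning rate decaying linearly to 0 over the last
60k steps.  Scaled runs keep the decay phase's absolute length rather
than its fraction: a 60k-step run anneals linearly from the start, which
empirically also suppresses the occasional late-training oscillations of
sign-gradient optimization (two of ten seeds plateau near 5-7 deg under a
compressed constant-then-decay schedule; none do under full-run
annealing).  Equilibrium analysis: the
student converges to ŷ = y* − β where β is the teacher's 0.5-crossing, so
a student's *inherited offset* −mean(signed error) recovers β with
slope 1 (the bias-inheritance relationship, verified for injected biases
±10°).  One numerical guard: raw azimuth outputs are kept within ±540°
by an inward surrogate sign outside that wall — angles live on the
circle, and without the wall a rare transient oscillation can push the
output past the range where wrapped-residual feedback still restores it
(the drift then runs away).  The wall is never active in converged runs.

**Intrinsic-reward policy gradient (midline teacher).**  Gaussian policy
a ~ N(μ(s), 3.6²); at most 3 roll-out steps; +100 on a teacher spike
(episode ends), −5 per step, episode also ends if the residual leaves
±90°; discount γ = 0.1; returns G_t = Σ γ^(k−t) r_k.  200k episodes,
batch 32, lr 3·10⁻⁴ decaying to 0 over the final 15%.  The update uses
∇log π·(G_t − b_t) with b_t the batch-mean return at roll-out step t — a
state-independent baseline that leaves the expected gradient unchanged
and removes the variance contributed by far sources whose returns carry
no action information; without it learning is unstable.  Errors
concentrate at the lateral extremes, where the ILD map flattens.

**Peak seeking (monaural teacher).**  Compare loudness at ŷ − ε, ŷ,
ŷ + ε (ε = 5°, probes clipped to the rotation limit) and follow the
louder side; the centre being loudest means aligned (zero gradient).
Feedback from a pose clipped at the rotation limit only reports the
source's side relative to the *pose*, so feedback that would push an
already-out-of-range prediction further out is dropped — without this the
refinement phase (sampling ±40° with rotation ±20°) diverges.

**Range expansion (3-D).**  Coordinates are relative to the right-ear
response peak (found by grid argmax).  Stage 1 learns ±30° in both axes by
sequential azimuth/elevation peak seeking (300k steps at full scale,
batch 4), then a refinement pass on ±40° with rotation ±20°.  Stages 2–6
sample from ±30°·i (azimuth capped at 180°, elevation at [−40°, 90°]); a
first prediction beyond the rotation limit triggers: rotate to the signed
limit ℓ, let the frozen previous-stage localiser predict the remainder
y₂, and train toward y₂ + ℓ (targets outside the stage range are
discarded and counted).  Weight duplication: the stage teacher is a
frozen copy of the current network.

## Problem sizes used by the test suite

The default suite runs everything at reduced scale: bootstrap runs use
60k steps with full-run annealing (10 seeds), the bias sweep 10k steps per teacher on the frontal
semicircle, the recalibration pipeline 20k-step retraining, reinforcement
learning the full 200k episodes (cheap in the level-domain environment),
and the spherical smoke test a 6k-step first phase.  `scripts/acceptance.py`
uses 60k steps.  At these sizes the bootstrap student reaches ≈3–5° MAE;
the full 160k-step schedule reaches ≈2–3° on the synthetic environment.

## What the synthetic generators do and do not capture

The LSO parameter generator emulates the *structure* of published LSO
datasets — sigmoid ILD tuning with per-neuron half-activation jitter
c ~ N(0, 3 dB), slopes d ~ U(1, 5) dB, power-law variability bounded by
30% of the rate range at 20 dB ILD — not any neuron's actual values.
Half-activation points are drawn as ±|N(0, 3)| pairs sharing (|c|, d)
within adjacent-cf pairs: marginals are unchanged, but the ensemble's
decision boundary stays within ~±2° of the midline (mirrored bilateral
innervation), matching the near-unbiased population teacher the learning
experiments assume.  Individual neurons remain biased discriminators, and
single-neuron teachers drawn from the table span biases of tens of
degrees.

The synthetic head model provides exactly the cues the task needs and no
more: smooth sinusoidal ILDs, one spectral front/back feature, one
elevation feature, and stationary chi-square level noise.  Real HRTFs
have individual notches, non-monotone ILD profiles and measurement noise;
passing tests on the synthetic model therefore demonstrate the learning
principles, not performance on any individual's ears.  The printed
headline errors of the reference experiments (2.7°/4.0°/2.4°/3.1°) depend
on a measured KEMAR set and an unpublished neuron table, and are
reproduced here only in magnitude.

## Known limitations

* **Asymmetric-scaling recalibration.**  With magnitudes pinned to dB SPL
  (identity ANF) a unilateral scaling by 0.5 shifts every neuron's ILD
  input by ~25 dB — far outside the generated ensemble's ±3 dB
  half-activation spread — saturating the population.  Dynamic-range
  adaptation restores a finite but shallow, noisy response (the power-law
  rate noise at |x| ≈ 35 dB is amplified by the narrow adapted range, and
  asymmetric gain makes the cue level-dependent under ±20 dB jitter), and
  two near-midline labels cannot then place a crisp boundary: the
  recalibrated teacher does not reach |β| < 3°, and retraining against it
  does not restore the student.  This severity is a direct consequence of
  the magnitude scale; at smaller magnitude scales (or with the tens-of-dB
  half-activation spread of real LSO data) the same pipeline recovers.
  The corresponding acceptance test is expected to fail and documents
  this.
* A symmetric 20 dB shift does not degrade the trained student at all —
  training with ±20 dB level jitter makes it level-invariant, and a
  symmetric band shift is exactly a level change.
* ITDs, spectral fine structure, reverberation, multiple sources and
  distance are out of scope by design.
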