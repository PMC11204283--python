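# Methods

This note records the models implemented in `lipwave`, the choices made
where the design was genuinely open, and what the simulated validation does
and does not demonstrate.

## Sensing model and attitude fusion

Each of the three IMUs (head, lip, chin) reports tri-axial specific force
(g units, range ±2 g) and angular rate (deg/s, range ±200 deg/s) at 100 Hz.
We use the reaction-force convention: a resting sensor reads +1 g along its
body z axis, so the accelerometer observation is `f = g_b − a_b + υ` with
`g_b` the gravity direction and `a_b` the linear acceleration, both in body
axes.

The per-sensor Kalman filter estimates the 6-state `x = [a_b, g_b]`:

- linear acceleration follows a first-order Gauss–Markov prior
  `da/dt = η a + w`, with `η = −2 s⁻¹` by default (0.5 s correlation time —
  the model only needs `η ≤ 0` for stability, and results are insensitive
  to its exact value at head-motion time scales);
- gravity propagates with the gyroscope through `dg/dt = −[ω×] g`; the
  discrete transition uses the exact Rodrigues form of `expm(−[ω×]Tₛ)`
  rather than a truncated series, so nothing degrades at fast rotations;
- the process covariance couples gyro noise into the gravity states via
  `σ_g² Tₛ² [g×][g×]ᵀ` evaluated at the current gravity estimate, which
  correctly assigns zero process noise along the gravity direction itself;
- the measurement model is `y = C x + υ`, `C = [−I₃ I₃]`, `R = σ_υ² I₃`.

Default noise figures are plausible consumer-IMU values: `σ_υ = 5·10⁻³ g`,
`σ_g = 0.1 deg/s`, `σ_a = 0.05 g`; all are per-sensor configurable and the
simulated protocols run at these defaults.  The filter is initialised from
the mean of the first 50 accelerometer samples (`g_b`), zero `a_b` and
`P = 0.01·I`; recordings are assumed to begin at rest, which the
calibration posture guarantees in practice.  The update uses the Joseph
covariance form so `P` stays symmetric positive semidefinite over long runs
(asserted over 10⁴ noisy steps in the tests).  Internally all angles are
radians; every interface is in degrees.

Pitch/roll follow from the gravity estimate as `γ = atan(g_y/g_z)`,
`θ = −atan(g_x cos γ / g_z)`, and the navigation-to-body matrix `M_nb` is
the standard pitch–roll composition with heading ignored (the interface
never resolves yaw; relative motion of articulators does not need it).

## Misalignment calibration and relative motion

The mounting rotation between a sensor case and its body segment is
estimated from two quasi-static postures: standing upright, then leaning
forward, each held a few seconds with the mouth closed.  The phase-1 mean
accelerometer direction fixes the body z axis in sensor coordinates; the
lean rotates gravity about the leftward body y axis, so
`y_b = unit(z_b × mean phase-2 accel)` and `x_b = y_b × z_b`.  The sign
convention makes a forward lean a *negative* pitch change.  A stillness
check (mean gyro norm < 3 deg/s) guards the posture requirement, and the
two phases must differ by at least 10° or calibration aborts (no lean
detected).  The residual diagnostic is the out-of-sagittal-plane angle of
the aligned phase-2 gravity.

Relative motion composes the three fused absolute attitudes:
`M_rel = M_nb_head⁻¹ M_nb_other`, with
`θ_rel = −atan(M_rel[0,2]/M_rel[0,0])`, `γ_rel = −atan(M_rel[2,1]/M_rel[1,1])`
and `ω_rel = M_nb_head M_nb_other⁻¹ ω_other − ω_head`.  Because all three
filters see the same head motion, common-mode rotation cancels in the
relative channels; only differential sensor noise and calibration error
remain.  The simulated turntable protocol (±60° sweep in 15° steps, 2 s
dwells, random mountings up to 30°, default noise) keeps the maximum
plateau error below 0.35°, and the head-rotation interference test keeps
relative-pitch leakage below 0.23° and relative-roll leakage below 0.32°
— the bounds reported for the physical system.  Plateau errors are read on
the settled second half of each dwell; 2 s dwells comfortably exceed the
filter settling time at default gains.

## Speech detection

The activity indicator is the per-sample norm
`ω_ind = sqrt(ω_Lx² + ω_Ly² + ω_Lz²)` of the lip's relative angular
velocity (the printed indicator formula is this Euclidean norm, and that is
what we implement), smoothed by a 35-sample moving average with step 1.
The window is centered — an offline choice that keeps onset/offset bias
symmetric; an online detector would lag by 17 samples.  The threshold is
2.5% of the indicator's per-person maximum (session maximum by default, or
a stored reference), with no hysteresis, and runs shorter than 50 samples
are discarded as non-speech movements.

## Synthetic motion generation

No recordings ship with the package; a seeded generator emulates every
input.  Word templates are sums of 3–6 random Gaussian bumps per channel,
windowed to rest at both ends, low-passed below 8 Hz and capped at 40°
amplitude (inside the ±60° articulation range the hardware was validated
over).  Word repetitions rescale duration (linear interpolation) and
amplitude by independent truncated-normal factors, emulating within-word
variability.  Ground-truth "actually spoken" sentences are produced by the
same segment–concatenate–smooth chain used for synthesis, with independent
per-word jitter, so the optimizer and decoder can be evaluated against a
known answer.

These templates are stylized stand-ins: they reproduce the smoothness,
band-limit, rest margins and variability of articulator motion, but make
no claim about real articulation morphology, coarticulation, or
skin-motion artifacts.  Passing tests therefore demonstrate correctness of
the algorithms under the stated motion model, not performance on human
speech.

## Sentence synthesis and augmentation

A sentence is reconstructed from its words in four steps: trim each word's
lead and end by its segmentation ratios (`floor(r·L)` samples each —
flooring never over-trims past the `r_l + r_e ≤ 1` constraint), concatenate
in order, and smooth the joints with a zero-phase 4th-order Butterworth
low-pass at 8 Hz (zero-phase so word timing is not warped; the filter
family/order were open and this is the conventional choice).  Repetition
index j of every word forms synthetic sentence j.

Augmentation draws, for each original repetition, 100 segmentation pairs
per word from a normal law centered on the optimum with a *relative* SD of
20% (floored at 20% of 0.05 when the optimum is 0, so a zero ratio still
explores), rejection-sampled into the feasible set; each word
independently rescales its length and magnitude by N(1, 0.2) truncated
positive.  Whether jitter is drawn per word or per sentence was not
specified; we draw per word per draw.  Rare tail draws that trim a draft
below the smoothing filter's warm-up are redrawn.  Defaults give
20 × 100 = 2000 augmented plus 20 plain syntheses = 2020 samples per
sentence.

## Segmentation-parameter estimation

The objective for a candidate vector `x = [r_l1, r_e1, …]` is the mean
normalized multivariate DTW distance between sentences synthesized under
`x` and the actual samples.  When the synthesized repetitions correspond
one-to-one with the actual recordings the pairs are matched by repetition
index; otherwise all (synthesized, actual) combinations are averaged
(capped at 12 for runtime).  Pairing matters: cross-repetition distances
add a large parameter-insensitive baseline that flattens the objective and
washes out the basin around the true ratios.  DTW uses the Euclidean
distance between 4-vectors as local cost and the classic recurrence
`D(i,j) = d(i,j) + min(D(i−1,j), D(i,j−1), D(i−1,j−1))`, normalized by
`n + m`; the inner loop is JIT-compiled (numba) with a pure NumPy fallback,
and is verified against exhaustive warping-path enumeration for all lengths
up to 8.

The Gaussian-process surrogate uses an ARD Matérn 5/2 kernel with Gaussian
observation noise; hyperparameters maximize the marginal likelihood by
L-BFGS-B with an analytic gradient, 5 seeded restarts, and a noise-SD floor
of 10⁻⁶ for conditioning.  The posterior is the standard
`μ = k*ᵀ(K+σ_n²I)⁻¹y`, `σ² = k** − k*ᵀ(K+σ_n²I)⁻¹k*`.  The prior mean is
zero; inside the optimization loop the surrogate is fitted to
`log(f + 10⁻³)` after mean-centering — the objective is nonnegative with a
sharp basin near zero, which a stationary kernel models far better on the
log scale, and far-field predictions then revert to the running mean
rather than to an optimistically low zero that would turn the search into
corner exploration.  Expected improvement is maximized over 2048
Latin-hypercube candidates folded into the per-word simplex
`{r ≥ 0, r_l + r_e ≤ 1}` plus Gaussian clouds around the incumbent whose
radius adapts trust-region style: it contracts when the incumbent stops
improving (a globally-fitted GP reports near-zero EI beside the incumbent,
so without contraction refinement stalls) and re-expands on success; on a
persistent stall the iteration descends the posterior mean inside the
region instead of EI.  Candidates whose synthesis degenerates (near-total
trim) are scored as the DTW distance of an empty utterance rather than
raising.

The loop starts from 8 random feasible vectors; the last quarter of the
evaluation budget (default 80 total) is spent on a coordinate pattern
search from the incumbent with a halving step (0.05 → 0.004).  This final
phase exists because the surrogate-driven loop reliably reaches the basin
but stalls near the feasible-set boundary — clipped candidate clouds
degenerate on the boundary faces — although the objective descends
monotonically to the optimum (verified by line scans); the direct
coordinate walk finishes the localization.  All refinement evaluations
count against the same budget and appear in the trace.  On ground-truth
sentences with known ratios (three words, repetition-matched actual
samples, zero jitter) the optimizer recovers all six ratios within ±0.05
in 9/10 seeded runs at budget 80.

Identifiability has limits worth knowing: trims that remove only silent
rest margins are nearly unobservable, because DTW warps through
low-amplitude segments at almost no cost.  The word generator therefore
places articulation promptly at word onset (short rest shoulders), which
matches how real word waveforms begin and keeps the trim ratios
observable.  Per-sentence parameter sets are stored as-is;
`average_params` provides the position-wise mean when one general set is
wanted across sentences.

## Decoder

The classifier stacks TCN residual blocks — two identical 1-D dilated
causal convolutions (kernel 2) plus an additive skip, with a width-1
projection when channel counts differ (first block: 4 → filters) — then
global average pooling over time and a softmax layer.  Dilations double per
block: 6 blocks (receptive field 127) for words, 7 (255) for sentences.
Convolutions use ReLU and He initialisation; we use plain initialisation
rather than weight normalisation, and no dropout — at the network widths
used here training is stable without them, and both would be
straightforward to add.  Pooling averages over the full padded length by
default (the simplest reading of global average pooling); masked pooling
over true lengths is available behind a flag.  Inputs are z-scored per
channel using training-split statistics only and zero-padded *after*
normalization, so the padded region is exactly zero.  Training uses Adam
(lr 10⁻³) with seeded shuffling; the whole network, its backpropagation and
the optimizer are implemented directly on NumPy arrays and are
deterministic per seed (verified bit-exact across runs).

The full-scale filter count is 400; the bundled tests and demo use 12–16
filters and a few epochs, which is ample for the synthetic corpora and
keeps a complete run on one CPU in minutes.

## Desk-scale validation sizes

The simulated experiments are sized for a desk, not a cluster, and these
sizes are the package's own defaults:

- turntable protocol: 9 plateaus × 2 axes, 2 s dwells, ~50 s of signal;
- interference test: ~40 s session covering pitch −25.6..19.3° and roll
  −18.3..26.8°;
- parameter recovery: 3-word sentences (6-D search), 2 actual samples,
  budget 80, 10 seeds;
- data-efficiency experiment: 15-word vocabulary, 10 sentences of 4 words,
  20 repetitions per word, reduced augmentation 20 × 20 (8 420-sample
  corpora total per run), tested on 5 independently jittered held-out
  samples per sentence, 5 seeds.  True per-word trim ratios are drawn from
  0.20–0.45: fluent speech drops a large share of each isolated word's
  lead-in and tail, so fluent sentences are much shorter than plain
  concatenation.  Under these conditions the decoder trained *only* on the
  synthetic corpus decodes the held-out sentences at ≥ 0.90 accuracy, while
  the same decoder trained on zero-parameter (untrimmed) synthesis scores
  far lower — the qualitative contrast that motivates estimating
  segmentation parameters at all.

## Known limitations

- No soft-tissue/skin-artifact biomechanics, no magnetometer, no audio.
- The calibration assumes a pure forward lean; a lean with a large lateral
  component would bias the recovered y axis.
- Attitude extraction is undefined at ±90° pitch/roll (gimbal degeneracy);
  articulator and head motion stay far from it.
- The decoder's padded-average pooling makes very long pad regions dilute
  features; masked pooling is available where corpora mix very different
  lengths.
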