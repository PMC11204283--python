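# lipwave

A silent-speech interface decodes intended speech from articulator motion
instead of sound. `lipwave` implements the full signal chain of a wearable
lip-language interface built from three inertial measurement units (IMUs) on
the head, lip and chin:

1. **Attitude fusion** — a per-sensor Kalman filter with state
   `x = [a_b, g_b]` (linear acceleration under a Gauss–Markov prior
   `ȧ = ηa + w`; gravity propagated by the gyroscope through
   `ġ = −[ω×]g`) turns raw accelerometer/gyroscope streams into absolute
   pitch θ and roll γ.
2. **Misalignment calibration** — a two-posture procedure (stand upright,
   lean forward) estimates each sensor's mounting rotation from gravity
   alone, and relative lip/chin-versus-head attitudes
   `M_rel = M_head⁻¹ M_other` cancel head motion, leaving the four speech
   channels θ_L, γ_L, θ_C, γ_C.
3. **Speech detection** — the smoothed norm of the lip's relative angular
   velocity, thresholded at 2.5% of its per-person maximum, delimits speech
   segments (minimum 50 samples at 100 Hz).
4. **Sentence synthesis** — continuous, fluent sentence waveforms are built
   from independent word samples by trimming each word's lead/end by ratios
   (r_l, r_e), concatenating, and smoothing with an 8 Hz zero-phase
   low-pass; Monte-Carlo augmentation (SD 20%) turns 20 word repetitions
   into 2020 sentence samples.
5. **Segmentation-parameter estimation** — the trim ratios are recovered by
   Bayesian optimization (ARD Matérn 5/2 Gaussian process, expected
   improvement) of the normalized multivariate DTW distance
   `f(x) = D(n,m)/(n+m)` between synthesized and actually spoken sentences,
   under the constraint r_l + r_e ≤ 1 per word.
6. **Decoding** — a temporal convolutional network (residual blocks of two
   dilated causal convolutions, kernel 2, dilations 1…32 for words / 1…64
   for sentences, global average pooling, softmax) classifies words or
   sentences; the sentence decoder trains **only** on the synthetic corpus.

No recordings are required anywhere: a seeded motion simulator
(`lipwave.motion_sim`, `lipwave.scenarios`) generates rigid-body head/lip/
chin rotations observed through misaligned, noisy IMUs as well as per-word
speech waveform templates, so the whole chain is testable end to end. The
TCN (including backpropagation and Adam), the DTW recurrence and the
GP/EI optimizer are implemented in the package on NumPy/SciPy.

## Worked example

Simulate the interference protocol — the head sweeps ±25° in pitch and roll
with the lip/chin sensors rigidly attached (no speech), so any reported
relative angle is head-motion leakage:

```python
>>> from lipwave.scenarios import run_interference_test
>>> run_interference_test(seed=1)
{'max_abs_theta_deg': 0.1512, 'max_abs_gamma_deg': 0.1205,
 'head_pitch_span': (-25.59, 19.31), 'head_roll_span': (-18.25, 26.77)}
```

While the head's absolute pitch swings over 45°, the lip/chin speech
channels move by at most ≈ 0.15° — the interface is effectively
head-motion-free. Recovering segmentation parameters from two simulated
"actually spoken" sentences of a three-word sentence with true ratios
(r_l, r_e) = (0.2, 0.1) per word:

```python
>>> import numpy as np
>>> from lipwave.scenarios import make_vocabulary
>>> from lipwave.motion_sim import sample_word, make_ground_truth_sentence
>>> from lipwave.segparam import optimize_segmentation, BoConfig
>>> vocab = make_vocabulary(3, seed=0)
>>> bank = {w: sample_word(t, n=4, length_sd=0.08, amp_sd=0.08, seed=5)
...         for w, t in vocab.items()}
>>> actual = [make_ground_truth_sentence([bank[w][j] for w in vocab],
...           [(0.2, 0.1)] * 3, 0.0, seed=j) for j in range(4)]
>>> params, trace = optimize_segmentation([bank[w] for w in vocab], actual,
...                                       BoConfig(budget=80, seed=0))
>>> np.round(params.vector, 3)
array([0.2  , 0.1  , 0.179, 0.079, 0.192, 0.1  ])
```

All six ratios come back within ±0.021 of the truth from 80 objective
evaluations. The end-to-end demo pipeline
(`lipwave run-all --seed 0 --out runs/demo`) chains simulation,
calibration, fusion, detection, parameter optimization, corpus synthesis
and decoder training, writing a JSON manifest per stage.

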