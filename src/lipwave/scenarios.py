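"""End-to-end simulated validation protocols.

These functions reproduce, in simulation, the bench protocols used to
validate the wearable interface: the two-posture misalignment calibration
followed by a +/-60 degree turntable sweep of the relative angle, and the
head-rotation interference test in which all three sensors move rigidly
together while no speech occurs.  They are also the source of the synthetic
word vocabulary and ground-truth sentences used to exercise the synthesis,
optimization and decoding stages.
"""

from __future__ import annotations

import numpy as np

from .fusion import FusionParams
from .motion_sim import (
    RigidTrajectory,
    SensorModel,
    WordTemplate,
    make_ground_truth_sentence,
    make_turntable_trajectory,
    make_word_template,
    random_misalignment,
    sample_word,
    simulate_imu_stream,
    static_trajectory,
)
from .relative import SENSORS, CalibrationResult, calibrate_misalignment, process_session
from .samples import ImuStream, SpeechSample
from .synthesis import SegmentationParams, SynthesisConfig, build_training_corpus

__all__ = [
    "simulate_calibration_phases",
    "run_turntable_protocol",
    "run_interference_test",
    "make_vocabulary",
    "make_sentence_book",
    "actual_sentence_samples",
]


def _sensor_models(
    rng: np.random.Generator,
    misalign_deg: float,
    sigma_v: float,
    sigma_g: float,
) -> dict[str, SensorModel]:
    return {
        name: SensorModel(
            misalignment=random_misalignment(rng, misalign_deg) if misalign_deg > 0 else np.eye(3),
            sigma_v=sigma_v,
            sigma_g=sigma_g,
            seed=int(rng.integers(2**31)),
        )
        for name in SENSORS
    }


def simulate_calibration_phases(
    sensors: dict[str, SensorModel],
    rng: np.random.Generator,
    lean_deg: float = 20.0,
    duration_s: float = 5.0,
    fs: float = 100.0,
) -> tuple[dict[str, ImuStream], dict[str, ImuStream]]:
    """Upright and lean-forward static recordings, shared by all sensors.

    Leaning forward pitches the whole head/lip/chin assembly by ``-lean_deg``
    (forward lean lowers the pitch angle under this sign convention).
    """
    upright = static_trajectory(duration_s, fs)
    lean = static_trajectory(duration_s, fs, theta=-lean_deg)
    phase1, phase2 = {}, {}
    for name, model in sensors.items():
        m1 = SensorModel(misalignment=model.misalignment, sigma_v=model.sigma_v,
                         sigma_g=model.sigma_g, seed=int(rng.integers(2**31)))
        m2 = SensorModel(misalignment=model.misalignment, sigma_v=model.sigma_v,
                         sigma_g=model.sigma_g, seed=int(rng.integers(2**31)))
        phase1[name] = simulate_imu_stream(upright, m1, name)
        phase2[name] = simulate_imu_stream(lean, m2, name)
    return phase1, phase2


def _plateau_errors(
    result, traj: RigidTrajectory, channel: str, settle_fraction: float = 0.5
) -> np.ndarray:
    """Per-sample |estimate - commanded| on the settled part of each dwell."""
    est = result[channel].to_numpy()
    cmd = traj.theta if channel.startswith("theta") else traj.gamma
    mask = traj.dwell_mask
    # keep only the tail of each dwell so the filter has settled
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    keep = np.zeros_like(mask)
    for start, stop in zip(edges[::2], edges[1::2]):
        cut = start + int((stop - start) * settle_fraction)
        keep[cut:stop] = True
    return np.abs(est[keep] - cmd[keep])


def run_turntable_protocol(
    seed: int = 0,
    misalign_deg: float = 30.0,
    sigma_v: float = 5e-3,
    sigma_g: float = 0.1,
    dwell_s: float = 2.0,
    calibrate: bool = True,
    fs: float = 100.0,
) -> dict:
    """Misalignment calibration followed by a +/-60 deg, 15 deg-step sweep.

    The head sensor stays still while the lip and chin sensors (each with
    its own random mounting misalignment) sweep the relative angle about the
    y axis (pitch) and then the x axis (roll).  Returns the maximum absolute
    relative-angle error on the dwell plateaus, overall and per axis.
    """
    rng = np.random.default_rng(seed)
    sensors = _sensor_models(rng, misalign_deg, sigma_v, sigma_g)
    calib: CalibrationResult | None = None
    if calibrate:
        phase1, phase2 = simulate_calibration_phases(sensors, rng, fs=fs)
        calib = calibrate_misalignment(phase1, phase2)
    errors = {}
    for axis in ("y", "x"):
        traj = make_turntable_trajectory(axis=axis, dwell_s=dwell_s, fs=fs)
        still = static_trajectory(traj.t[-1] + traj.ts, fs)
        streams = {}
        for name in SENSORS:
            model = SensorModel(
                misalignment=sensors[name].misalignment,
                sigma_v=sigma_v, sigma_g=sigma_g, seed=int(rng.integers(2**31)),
            )
            moving = still if name == "head" else traj
            streams[name] = simulate_imu_stream(moving, model, name)
        result = process_session(streams, calib, FusionParams(ts=1.0 / fs))
        chans = ("theta_L", "theta_C") if axis == "y" else ("gamma_L", "gamma_C")
        errors[axis] = max(float(_plateau_errors(result, traj, ch).max()) for ch in chans)
    return {
        "max_error_deg": max(errors.values()),
        "per_axis": errors,
        "calibrated": calibrate,
    }


def _sweep_curve(n: int, lo: float, hi: float) -> np.ndarray:
    """Smooth 0 -> hi -> lo -> 0 excursion over n samples (lo <= 0 <= hi)."""
    u = np.linspace(0.0, 2.0 * np.pi, n)
    curve = np.sin(u)
    return np.where(curve >= 0, curve * hi, curve * (-lo))


def run_interference_test(
    seed: int = 0,
    pitch_range: tuple[float, float] = (-25.60, 19.33),
    roll_range: tuple[float, float] = (-18.28, 26.80),
    segment_s: float = 12.0,
    misalign_deg: float = 30.0,
    sigma_v: float = 5e-3,
    sigma_g: float = 0.1,
    fs: float = 100.0,
) -> dict:
    """Head-rotation interference test with rigidly co-moving lip/chin.

    All three sensors share one head trajectory (a pitch excursion spanning
    ``pitch_range``, then a roll excursion spanning ``roll_range``); any
    nonzero relative angle reported by the pipeline is head-motion leakage.
    Returns the max absolute relative pitch/roll over the session.
    """
    rng = np.random.default_rng(seed)
    n_seg = int(segment_s * fs)
    n_pad = int(2.0 * fs)
    pitch = np.concatenate([
        np.zeros(n_pad),
        _sweep_curve(n_seg, *pitch_range),
        np.zeros(n_seg + n_pad),
    ])
    roll = np.concatenate([
        np.zeros(n_pad + n_seg),
        _sweep_curve(n_seg, *roll_range),
        np.zeros(n_pad),
    ])
    t = np.arange(pitch.size) / fs
    traj = RigidTrajectory.from_angles(t, pitch, roll)
    sensors = _sensor_models(rng, misalign_deg, sigma_v, sigma_g)
    phase1, phase2 = simulate_calibration_phases(sensors, rng, fs=fs)
    calib = calibrate_misalignment(phase1, phase2)
    streams = {
        name: simulate_imu_stream(
            traj,
            SensorModel(misalignment=sensors[name].misalignment,
                        sigma_v=sigma_v, sigma_g=sigma_g, seed=int(rng.integers(2**31))),
            name,
        )
        for name in SENSORS
    }
    result = process_session(streams, calib, FusionParams(ts=1.0 / fs))
    settle = int(1.0 * fs)  # discard filter start-up
    r = result.iloc[settle:]
    return {
        "max_abs_theta_deg": float(r[["theta_L", "theta_C"]].abs().max().max()),
        "max_abs_gamma_deg": float(r[["gamma_L", "gamma_C"]].abs().max().max()),
        "head_pitch_span": (float(r["theta_H_abs"].min()), float(r["theta_H_abs"].max())),
        "head_roll_span": (float(r["gamma_H_abs"].min()), float(r["gamma_H_abs"].max())),
    }


# ---------------------------------------------------------------------------
# Synthetic vocabulary / sentence-book helpers
# ---------------------------------------------------------------------------


def make_vocabulary(
    n_words: int = 15,
    seed: int = 0,
    length_range: tuple[int, int] = (70, 110),
    fs: float = 100.0,
) -> dict[str, WordTemplate]:
    """Distinct synthetic word templates named w00, w01, ..."""
    rng = np.random.default_rng(seed)
    vocab = {}
    for i in range(n_words):
        wid = f"w{i:02d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        vocab[wid] = make_word_template(wid, nominal_length=length, seed=seed + i, fs=fs)
    return vocab


def make_sentence_book(
    vocab_ids: list[str],
    n_sentences: int = 10,
    words_per_sentence: int = 3,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Sentences as ordered word-id lists with pairwise distinct word sets.

    Word *sets* are kept distinct (not just orderings) because the decoder
    pools over time and is largely order-insensitive.
    """
    rng = np.random.default_rng(seed)
    book: dict[str, list[str]] = {}
    seen: set[frozenset] = set()
    tries = 0
    while len(book) < n_sentences:
        tries += 1
        if tries > 1000 * n_sentences:
            raise RuntimeError("vocabulary too small for distinct sentences")
        words = list(rng.choice(vocab_ids, size=words_per_sentence, replace=False))
        key = frozenset(words)
        if key in seen:
            continue
        seen.add(key)
        book[f"s{len(book):02d}"] = [str(w) for w in words]
    return book


def actual_sentence_samples(
    sentence_words: list[str],
    vocab: dict[str, WordTemplate],
    true_params: SegmentationParams,
    n_samples: int = 5,
    jitter_sd: float = 0.10,
    word_sd: float = 0.10,
    seed: int = 0,
) -> list[SpeechSample]:
    """Independently jittered 'actually spoken' sentence stand-ins.

    Each sample draws fresh word repetitions (length/amplitude SD
    ``word_sd``), applies additional per-word jitter ``jitter_sd``, then the
    segment-concatenate-smooth chain with the true parameters.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_samples):
        words = [
            sample_word(vocab[w], n=1, length_sd=word_sd, amp_sd=word_sd,
                        seed=int(rng.integers(2**31)))[0]
            for w in sentence_words
        ]
        out.append(
            make_ground_truth_sentence(
                words, true_params.ratios, jitter_sd=jitter_sd, seed=int(rng.integers(2**31))
            )
        )
    return out


def data_efficiency_experiment(
    seed: int = 0,
    n_words: int = 15,
    n_sentences: int = 10,
    words_per_sentence: int = 4,
    reps: int = 20,
    pairs_per_sample: int = 20,
    n_test_per_sentence: int = 5,
    ratio_range: tuple[float, float] = (0.2, 0.45),
    filters: int = 16,
    epochs: int = 5,
    zero_params: bool = False,
) -> dict:
    """Sentence decoding trained purely on the synthetic corpus.

    Builds a word bank from a synthetic vocabulary, synthesizes + augments a
    training corpus per sentence with the true segmentation parameters (or
    all-zero parameters when ``zero_params``), trains the 7-block sentence
    decoder on it alone, and tests on independently jittered ground-truth
    sentences never seen in training.  The true per-word trim ratios are
    drawn from ``ratio_range``: fluent speech drops a substantial share of
    each isolated word's lead-in and tail, so sentences are much shorter
    than plain word concatenation.  Returns the test accuracy and sizes.
    """
    from . import decoder as dec

    rng = np.random.default_rng(seed)
    vocab = make_vocabulary(n_words, seed=seed)
    book = make_sentence_book(list(vocab), n_sentences, words_per_sentence, seed=seed)
    true_params = {
        sid: SegmentationParams(
            ratios=[(float(r), float(e)) for r, e in
                    rng.uniform(*ratio_range, size=(len(w), 2))]
        )
        for sid, w in book.items()
    }
    bank = {
        w: sample_word(t, n=reps, length_sd=0.1, amp_sd=0.1, seed=seed + 17)
        for w, t in vocab.items()
    }
    train_params = (
        {sid: SegmentationParams(ratios=[(0.0, 0.0)] * len(w)) for sid, w in book.items()}
        if zero_params
        else true_params
    )
    cfg = SynthesisConfig(pairs_per_sample=pairs_per_sample, seed=seed)
    corpus, manifest = build_training_corpus(book, bank, train_params, cfg)
    test = [
        s.copy(label=sid)
        for sid, words in book.items()
        for s in actual_sentence_samples(
            words, vocab, true_params[sid], n_samples=n_test_per_sentence,
            jitter_sd=0.05, word_sd=0.1, seed=seed + 29,
        )
    ]
    ds = dec.prepare_train_test(corpus, test)
    dcfg = dec.DecoderConfig(n_blocks=7, filters=filters, epochs=epochs,
                             batch_size=64, seed=seed)
    model = dec.build(dcfg, len(ds.classes), ds.max_length)
    history = dec.train(model, ds, dcfg)
    metrics = dec.evaluate(model, ds)
    return {
        "accuracy": metrics["accuracy"],
        "n_train": len(corpus),
        "per_sentence": manifest["sentences"][next(iter(book))]["total"],
        "n_test": len(test),
        "final_loss": history["loss"][-1],
    }
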