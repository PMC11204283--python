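"""Artificial continuous-sentence synthesis from independent word samples.

A sentence waveform is reconstructed from its words in four steps: trim each
word at the lead and end by its segmentation ratios, concatenate the trimmed
waveforms in order, smooth the joints with an 8 Hz zero-phase low-pass, and
(for augmentation) repeat with Monte-Carlo perturbed segmentation ratios and
per-word length/amplitude factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .samples import SpeechSample


def _stable_id(name: str) -> int:
    """Process-independent 31-bit hash of an identifier (seeding)."""
    import zlib

    return zlib.crc32(name.encode()) % 2**31

__all__ = [
    "SegmentationParams",
    "SynthesisConfig",
    "segment_word",
    "concatenate_words",
    "smooth_transitions",
    "synthesize_sentence",
    "augment_sentence",
    "build_training_corpus",
]


@dataclass
class SegmentationParams:
    """Per-word lead/end trim ratios, constrained to r_l + r_e <= 1."""

    ratios: list[tuple[float, float]]

    def __post_init__(self) -> None:
        for r_l, r_e in self.ratios:
            _check_pair(r_l, r_e)

    @property
    def vector(self) -> np.ndarray:
        """Flattened [r_l1, r_e1, r_l2, r_e2, ...] layout."""
        return np.array([v for pair in self.ratios for v in pair])

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "SegmentationParams":
        x = np.asarray(x, dtype=float)
        if x.size % 2:
            raise ValueError("parameter vector length must be even")
        return cls(ratios=[(float(x[i]), float(x[i + 1])) for i in range(0, x.size, 2)])

    def __len__(self) -> int:
        return len(self.ratios)


def _check_pair(r_l: float, r_e: float) -> None:
    if r_l < 0 or r_e < 0:
        raise ValueError("segmentation ratios must be >= 0")
    if r_l + r_e > 1:
        raise ValueError(f"constraint violated: r_l + r_e = {r_l + r_e:.3f} > 1")


@dataclass
class SynthesisConfig:
    """Synthesis and augmentation settings.

    ``cutoff_hz`` (default 8) is the transition-smoothing low-pass corner;
    ``pairs_per_sample`` (default 100) Monte-Carlo segmentation draws per
    original word repetition; ``mc_sd`` the relative SD (default 0.20) of
    both the parameter and the length/amplitude perturbations.
    """

    cutoff_hz: float = 8.0
    fs: float = 100.0
    pairs_per_sample: int = 100
    mc_sd: float = 0.20
    ratio_sd_floor: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cutoff_hz >= self.fs / 2:
            raise ValueError("cutoff must be below Nyquist")
        if self.mc_sd < 0:
            raise ValueError("Monte-Carlo SD must be >= 0")


def segment_word(sample: SpeechSample, r_l: float, r_e: float) -> SpeechSample:
    """Trim floor(r_l*L) leading and floor(r_e*L) trailing samples."""
    _check_pair(r_l, r_e)
    n = sample.length
    lead = int(np.floor(r_l * n))
    tail = int(np.floor(r_e * n))
    if n - lead - tail <= 0:
        raise ValueError("degenerate trim: nothing left of the word")
    return sample.copy(data=sample.data[:, lead : n - tail])


def concatenate_words(trimmed: list[SpeechSample]) -> SpeechSample:
    """Channel-wise end-to-end concatenation preserving word order."""
    if not trimmed:
        raise ValueError("nothing to concatenate")
    fs = trimmed[0].fs
    if any(s.fs != fs for s in trimmed):
        raise ValueError("samples must share a sampling rate")
    data = np.concatenate([s.data for s in trimmed], axis=1)
    label = " ".join(s.label for s in trimmed)
    return SpeechSample(data=data, label=label, fs=fs)


def smooth_transitions(draft: SpeechSample, config: SynthesisConfig | None = None) -> SpeechSample:
    """Zero-phase 4th-order Butterworth low-pass (default 8 Hz) per channel."""
    cfg = config or SynthesisConfig()
    b, a = butter(4, cfg.cutoff_hz / (cfg.fs / 2), btype="low")
    padlen = 3 * (max(len(a), len(b)) - 1)
    if draft.length <= padlen:
        raise ValueError(f"waveform too short to filter (need > {padlen} samples)")
    return draft.copy(data=filtfilt(b, a, draft.data, axis=1))


def synthesize_sentence(
    word_sample_sets: list[list[SpeechSample]],
    params: SegmentationParams,
    config: SynthesisConfig | None = None,
) -> list[SpeechSample]:
    """Segment-concatenate-smooth one sentence, per repetition index.

    ``word_sample_sets[i]`` holds the repetitions of the i-th word of the
    sentence; repetition j of every word forms synthetic sentence j.
    """
    cfg = config or SynthesisConfig()
    if len(word_sample_sets) != len(params):
        raise ValueError("one (r_l, r_e) pair per word required")
    counts = {len(s) for s in word_sample_sets}
    if len(counts) != 1:
        raise ValueError("words must have equal repetition counts for pairing")
    (n_rep,) = counts
    out = []
    for j in range(n_rep):
        trimmed = [
            segment_word(word_sample_sets[i][j], *params.ratios[i])
            for i in range(len(word_sample_sets))
        ]
        out.append(smooth_transitions(concatenate_words(trimmed), cfg))
    return out


def _draw_feasible_pair(
    rng: np.random.Generator, r_l: float, r_e: float, cfg: SynthesisConfig
) -> tuple[float, float]:
    """Perturb a ratio pair by a relative-SD normal, kept in the feasible set.

    The SD is ``mc_sd`` times the mean ratio, floored at ``mc_sd *
    ratio_sd_floor`` so a zero optimum still explores.  Rejection sampling
    into {r >= 0, r_l + r_e <= 1}, clipping after 100 tries.
    """
    sd_l = cfg.mc_sd * max(r_l, cfg.ratio_sd_floor)
    sd_e = cfg.mc_sd * max(r_e, cfg.ratio_sd_floor)
    for _ in range(100):
        a = rng.normal(r_l, sd_l)
        b = rng.normal(r_e, sd_e)
        if a >= 0 and b >= 0 and a + b <= 1:
            return a, b
    a = min(max(a, 0.0), 1.0)
    b = min(max(b, 0.0), 1.0 - a)
    return a, b


def _positive_factor(rng: np.random.Generator, sd: float) -> float:
    if sd == 0:
        return 1.0
    for _ in range(100):
        v = rng.normal(1.0, sd)
        if v > 0.05:
            return v
    return 0.05


def augment_sentence(
    word_sample_sets: list[list[SpeechSample]],
    optimal_params: SegmentationParams,
    config: SynthesisConfig | None = None,
) -> list[SpeechSample]:
    """Monte-Carlo augmentation around the optimal segmentation.

    For every original repetition index, ``pairs_per_sample`` segmentation
    draws are taken around the optimum and each word additionally changes
    its length and magnitude by independent N(1, mc_sd) factors before the
    usual segment-concatenate-smooth chain.  Defaults give 20 x 100 = 2000
    augmented sentences.
    """
    from .motion_sim import _rescale_length  # local import avoids a cycle

    cfg = config or SynthesisConfig()
    for r_l, r_e in optimal_params.ratios:
        _check_pair(r_l, r_e)
    counts = {len(s) for s in word_sample_sets}
    if len(counts) != 1:
        raise ValueError("words must have equal repetition counts")
    (n_rep,) = counts
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    out = []
    for j in range(n_rep):
        for _ in range(cfg.pairs_per_sample):
            # redraw the rare tail events that trim a draft below the
            # smoothing filter's warm-up length
            for _attempt in range(20):
                try:
                    trimmed = []
                    for i, (r_l, r_e) in enumerate(optimal_params.ratios):
                        a, b = _draw_feasible_pair(rng, r_l, r_e, cfg)
                        word = word_sample_sets[i][j]
                        lf = _positive_factor(rng, cfg.mc_sd)
                        af = _positive_factor(rng, cfg.mc_sd)
                        jittered = word.copy(data=_rescale_length(word.data, lf) * af)
                        trimmed.append(segment_word(jittered, a, b))
                    out.append(smooth_transitions(concatenate_words(trimmed), cfg))
                    break
                except ValueError:
                    continue
            else:
                raise ValueError("augmentation cannot produce a filterable draft")
    return out


def build_training_corpus(
    sentences: dict[str, list[str]],
    word_bank: dict[str, list[SpeechSample]],
    params: dict[str, SegmentationParams],
    config: SynthesisConfig | None = None,
) -> tuple[list[SpeechSample], dict]:
    """Full synthetic corpus: per sentence, plain syntheses plus augmentation.

    ``sentences`` maps sentence id -> ordered word ids; ``params`` maps
    sentence id -> its SegmentationParams.  With defaults each sentence
    yields 20 optimal-parameter syntheses + 2000 augmented = 2020 samples.
    Returns (samples labeled by sentence id, manifest).
    """
    cfg = config or SynthesisConfig()
    corpus: list[SpeechSample] = []
    manifest: dict = {"seed": cfg.seed, "sentences": {}}
    for sid, word_ids in sentences.items():
        missing = [w for w in word_ids if w not in word_bank]
        if missing:
            raise KeyError(f"words missing from the bank: {missing}")
        sets = [word_bank[w] for w in word_ids]
        p = params[sid]
        scfg = SynthesisConfig(
            cutoff_hz=cfg.cutoff_hz,
            fs=cfg.fs,
            pairs_per_sample=cfg.pairs_per_sample,
            mc_sd=cfg.mc_sd,
            ratio_sd_floor=cfg.ratio_sd_floor,
            seed=int(np.random.SeedSequence([cfg.seed, _stable_id(sid)]).generate_state(1)[0] % 2**31),
        )
        plain = synthesize_sentence(sets, p, scfg)
        augmented = augment_sentence(sets, p, scfg)
        for s in plain + augmented:
            corpus.append(s.copy(label=sid))
        manifest["sentences"][sid] = {
            "words": list(word_ids),
            "plain": len(plain),
            "augmented": len(augmented),
            "total": len(plain) + len(augmented),
            "seed": scfg.seed,
        }
    manifest["total"] = len(corpus)
    return corpus, manifest
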