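"""Threshold-based speech activity detection on the relative-motion stream.

The activity indicator is the per-sample norm of the lip's relative angular
velocity.  It is smoothed by a centered 35-sample moving average, thresholded
at 2.5% of its per-person maximum, and runs shorter than 50 samples are
discarded as non-speech lip/chin movements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DetectorConfig", "SpeechSegment", "activity_indicator", "smooth_indicator", "detect_segments"]


@dataclass
class DetectorConfig:
    window: int = 35
    step: int = 1
    threshold_fraction: float = 0.025
    min_length: int = 50

    def __post_init__(self) -> None:
        if self.window < 1 or self.min_length < 1:
            raise ValueError("window and minimum length must be >= 1")
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold fraction must be in (0, 1)")


@dataclass
class SpeechSegment:
    """Inclusive [start, end] indices plus the extracted 4-channel waveform."""

    start: int
    end: int
    waveform: np.ndarray

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("segment end before start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def activity_indicator(omega_l: np.ndarray) -> np.ndarray:
    """sqrt(wx^2 + wy^2 + wz^2) per sample for a (T, 3) lip angular velocity."""
    omega_l = np.asarray(omega_l, dtype=float)
    return np.linalg.norm(omega_l, axis=-1)


def smooth_indicator(omega_ind: np.ndarray, config: DetectorConfig | None = None) -> np.ndarray:
    """Centered moving average (truncated windows at the edges)."""
    cfg = config or DetectorConfig()
    x = np.asarray(omega_ind, dtype=float)
    if x.size < cfg.window:
        raise ValueError("sequence shorter than the smoothing window")
    kernel = np.ones(cfg.window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def detect_segments(
    smoothed: np.ndarray,
    config: DetectorConfig | None = None,
    frames: pd.DataFrame | None = None,
    reference_max: float | None = None,
) -> list[SpeechSegment]:
    """Maximal above-threshold runs, dropping those shorter than min_length.

    The threshold is ``threshold_fraction`` of the per-person maximum of the
    smoothed indicator (the session max unless ``reference_max`` supplies a
    stored one).  If ``frames`` carries the relative-motion channels, each
    segment's (4, T) waveform is extracted; otherwise waveforms are empty.
    """
    cfg = config or DetectorConfig()
    x = np.asarray(smoothed, dtype=float)
    ref = reference_max if reference_max is not None else (x.max() if x.size else 0.0)
    if ref <= 0:
        return []
    thresh = cfg.threshold_fraction * ref
    active = x >= thresh
    segments: list[SpeechSegment] = []
    idx = np.flatnonzero(np.diff(np.concatenate([[0], active.view(np.int8), [0]])))
    for start, stop in zip(idx[::2], idx[1::2]):
        end = stop - 1
        if stop - start < cfg.min_length:
            continue
        if frames is not None:
            wf = frames.iloc[start:stop][["theta_L", "gamma_L", "theta_C", "gamma_C"]].to_numpy().T
        else:
            wf = np.empty((4, 0))
        segments.append(SpeechSegment(start=int(start), end=int(end), waveform=wf))
    return segments
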