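"""Serializable run configuration covering every pipeline stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from .decoder import DecoderConfig
from .detection import DetectorConfig
from .fusion import FusionParams
from .io import load_json, save_json
from .segparam import BoConfig
from .synthesis import SynthesisConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Global seed plus per-stage configurations; JSON round-trips exactly."""

    seed: int = 0
    out_dir: str = "runs/demo"
    log_level: str = "INFO"
    fusion: FusionParams = field(default_factory=FusionParams)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    synthesis: SynthesisConfig = field(default_factory=SynthesisConfig)
    bo: BoConfig = field(default_factory=BoConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    # demo-scale knobs for the end-to-end run
    n_words: int = 6
    n_sentences: int = 3
    words_per_sentence: int = 2

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = dict(d)
        for name, sub in (
            ("fusion", FusionParams),
            ("detector", DetectorConfig),
            ("synthesis", SynthesisConfig),
            ("bo", BoConfig),
            ("decoder", DecoderConfig),
        ):
            if name in kw and isinstance(kw[name], dict):
                allowed = {f.name for f in fields(sub)}
                kw[name] = sub(**{k: v for k, v in kw[name].items() if k in allowed})
        return cls(**kw)

    def save(self, path: str | Path) -> None:
        save_json(path, self.to_dict())

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(load_json(path))
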