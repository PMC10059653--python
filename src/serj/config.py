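"""Run configuration: one strict, hashable document covering every stage."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CalibrationConfig(_Strict):
    mode: str = "off"  # "off" | "divide"
    a: float = 2014.0
    b: float = 2.0
    c: float = 10000.0
    d: float = 512.0


class WaveletConfig(_Strict):
    name: str = "db4"
    levels: int = 3
    rule: str = "universal"
    mode: str = "soft"


class FilterConfig(_Strict):
    cutoff_hz: float = 10.0
    order: int = 4


class PreprocessConfig(_Strict):
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    wavelet: WaveletConfig = Field(default_factory=WaveletConfig)
    filter: FilterConfig = Field(default_factory=FilterConfig)


class FeaturesConfig(_Strict):
    signed_diffs: bool = False  # BpNN50 on signed rather than absolute differences
    pnn_threshold_ms: float = 50.0


class SelectionConfig(_Strict):
    variance_target: float = 0.9
    weight_threshold: float | str = 0.5  # "mean": mean communality across features
    alpha: float = 0.05
    r_min: float = 0.3


class JudgeConfig(_Strict):
    calibration_windows: int = 4
    window_length_s: float = 10.0


class BaselineConfig(_Strict):
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str = "scale"
    split: float = 0.7


class AdaptationConfig(_Strict):
    persistence: int = 1
    refractory: int = 1
    session_end_after_new_scenes: int = 2


class RunConfig(_Strict):
    seed: int = 0
    fs: float = 100.0
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    features: FeaturesConfig = Field(default_factory=FeaturesConfig)
    selection: SelectionConfig = Field(default_factory=SelectionConfig)
    judge: JudgeConfig = Field(default_factory=JudgeConfig)
    baseline: BaselineConfig = Field(default_factory=BaselineConfig)
    adaptation: AdaptationConfig = Field(default_factory=AdaptationConfig)

    def config_hash(self) -> str:
        """Stable hash over all semantic fields."""
        doc = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})
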