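"""Run configuration and trial bundles for the processing pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .models import MODEL_IDS

__all__ = ["RunConfig", "TrialBundle", "TRIAL_TYPES"]

TRIAL_TYPES = ("static", "calf_raise", "gait", "drop_jump", "dummy_sweep")


@dataclass
class TrialBundle:
    """One recorded trial: file reference, type and optional event window."""

    path: str
    trial_type: str
    window: tuple[int, int] | None = None
    subject: str = ""
    side: str = "right"
    rate: float | None = None  # required for CSV inputs

    def __post_init__(self) -> None:
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(
                f"trial type {self.trial_type!r} not in {TRIAL_TYPES}"
            )
        if self.side not in ("right", "left"):
            raise ValueError("side must be 'right' or 'left'")
        if self.window is not None:
            start, stop = self.window
            if start < 0 or stop <= start:
                raise ValueError(f"invalid event window {self.window}")


@dataclass
class RunConfig:
    """Validated parameters of one pipeline run.

    Defaults follow the measurement protocol: 6 Hz cutoff, 4th-order
    zero-lag Butterworth, intrinsic z-x'-y'' Cardan sequence, filtering
    applied to marker displacements before frame construction.
    """

    model: str = "new"
    euler_convention: str = "intrinsic"
    filter_cutoff_hz: float = 6.0
    filter_order: int = 4
    filter_stage: str = "markers"  # "markers" | "angles" | "off"
    baseline: str = "static"       # "static" | "off"
    noise_sigma: float = 0.0
    seed: int = 0
    out_dir: str = "footkin_out"

    def validate(self, rate: float | None = None) -> "RunConfig":
        """Check the configuration; raises before any file is touched."""
        if self.model not in MODEL_IDS:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODEL_IDS}")
        if self.euler_convention not in ("intrinsic", "extrinsic"):
            raise ValueError("euler_convention must be 'intrinsic' or 'extrinsic'")
        if self.filter_stage not in ("markers", "angles", "off"):
            raise ValueError("filter_stage must be 'markers', 'angles' or 'off'")
        if self.baseline not in ("static", "off"):
            raise ValueError("baseline must be 'static' or 'off'")
        if self.filter_cutoff_hz <= 0:
            raise ValueError("filter cutoff must be positive")
        if self.filter_order < 1:
            raise ValueError("filter order must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if rate is not None and self.filter_stage != "off" and self.filter_cutoff_hz >= rate / 2:
            raise ValueError(
                f"cutoff {self.filter_cutoff_hz} Hz must be below Nyquist ({rate / 2} Hz)"
            )
        return self

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        doc = yaml.safe_load(text) or {}
        return cls(**doc).validate()

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())
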