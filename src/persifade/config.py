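"""Run configuration with explicit defaults and lossless YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Tuple, Union

import yaml

from .geometry import AnnulusConvention

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything needed to regenerate a full simulate -> analyze run."""

    # display geometry
    matrix_px: int = 600
    matrix_deg: float = 19.15
    convention: str = AnnulusConvention.DIAMETER_DIFF.value
    # decay model defaults
    decay_a_rate: float = 50.0          # s^-1
    decay_threshold: float = 0.01
    decay_rate_ratio: float = 1.2
    decay_t_off_s: float = 0.6
    # observer / design
    experiment: int = 1
    n_subjects: int = 9
    reps: int = 20
    judgment_noise_sd_ms: float = 30.0
    confirm_jnd_ms: float = 20.0
    # filling-in regression feature choice
    fillin_use_printed_thickness: bool = False
    # provenance
    seed: int = 0
    out_dir: str = "out"

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False),
                              encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
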