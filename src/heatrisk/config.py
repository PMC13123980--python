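"""Pipeline configuration: one JSON-serialisable object drives a full run.

The master seed is the single source of randomness; every stage derives its
own seed deterministically from (master seed, stage label), so a rerun with
the same configuration reproduces every artifact.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from .synthetic import SyntheticConfig

__all__ = ["PipelineConfig"]


@dataclasses.dataclass
class PipelineConfig:
    """Everything a pipeline run needs, serialisable to/from JSON."""

    # input: either a synthetic generator config, the Dhaka-like preset, or
    # two wide-format files
    synthetic: dict | None = None
    use_dhaka_preset: bool = False
    temp_path: str | None = None
    rh_path: str | None = None

    split_boundary: str = "2022-01-01"
    models: list = dataclasses.field(default_factory=lambda: ["naive", "rfr"])
    hyperparameters: dict = dataclasses.field(default_factory=dict)
    cv_models: list = dataclasses.field(default_factory=list)
    cv_folds: int = 5

    scenarios: list = dataclasses.field(
        default_factory=lambda: ["optimistic", "moderate", "pessimistic"]
    )
    projection_model: str = "rfr"
    horizon_start: str = "2024-01-01"
    horizon_end: str = "2027-12-31"

    steadman_mode: str = "paper"
    master_seed: int = 0
    output_dir: str = "heatrisk_output"

    def synthetic_config(self, seed: int) -> SyntheticConfig | None:
        if self.synthetic is None:
            return None
        return SyntheticConfig(**{**self.synthetic, "seed": seed})

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        path = Path(source)
        payload = json.loads(path.read_text() if path.exists() else str(source))
        return cls(**payload)
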