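"""Run configuration for the end-to-end pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from ._errors import ConfigurationError
from .segment import ShapeCriteria

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serializable to/from YAML.

    ``phase_channel`` and ``fluor_channels`` are 0-based indices into the
    hyperstack's channel axis; exactly one phase channel is required.
    ``channel_classes`` maps fluorescence channel → "volume" (cytoplasmic)
    or "wall" (envelope-bound) for concentration plots.  ``n_avg`` maps
    channel → proteins per average cell for molecule-count calibration.
    """

    input_path: Optional[str] = None
    output_dir: str = "rodquant_out"
    px_per_um: Optional[float] = 14.98
    phase_channel: int = 0
    fluor_channels: list[int] = field(default_factory=lambda: [1])
    leader_channel: Optional[int] = None
    channel_classes: dict[int, str] = field(default_factory=dict)
    n_avg: dict[int, float] = field(default_factory=dict)
    midcell_halfwidth: float = 0.4
    age_bin_pct: float = 5.0
    n_age_groups: int = 10
    registration_max_shift: int = 5
    psf_margin_px: int = 4
    criteria: ShapeCriteria = field(default_factory=ShapeCriteria)
    qualifier: Optional[str] = None  # pandas query selecting cells to disqualify
    seed: int = 0

    def __post_init__(self) -> None:
        if self.midcell_halfwidth <= 0:
            raise ConfigurationError("midcell_halfwidth must be positive")
        if self.phase_channel in self.fluor_channels:
            raise ConfigurationError(
                "phase_channel must not be listed among fluor_channels"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "criteria" in d and isinstance(d["criteria"], dict):
            crit = dict(d["criteria"])
            if "diameter_range" in crit:
                crit["diameter_range"] = tuple(crit["diameter_range"])
            d["criteria"] = ShapeCriteria(**crit)
        for key in ("channel_classes", "n_avg"):
            if key in d and d[key]:
                d[key] = {int(k): v for k, v in d[key].items()}
        return cls(**d)


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a YAML config file, applying keyword overrides."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig.from_dict(data)
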