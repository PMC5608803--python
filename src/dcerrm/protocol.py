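"""Acquisition protocol for the PD-reference DCE-MRI scheme.

The dynamic T1-weighted series is a spoiled 3D gradient-echo (FLASH) scan
with short TR and a large flip angle; a single proton-density-weighted FLASH
scan with long TR and a small flip angle serves as the reference from which
T1 maps are computed frame by frame.  Defaults follow the study protocol:
reference TR = 100 ms / FA = 5 deg, dynamic TR = 8.09 ms / FA = 30 deg,
frame spacing 13.32 s, 40 frames of which the first 3 are pre-contrast.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = ["AcquisitionProtocol"]


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Sequence timing and flip angles of the reference and dynamic scans.

    All times are positive; flip angles are in degrees in (0, 90]; at least
    one pre-contrast (baseline) frame is required and baseline frames must
    not exhaust the dynamic series.
    """

    tr_ref_ms: float = 100.0
    fa_ref_deg: float = 5.0
    tr_dce_ms: float = 8.09
    fa_dce_deg: float = 30.0
    dt_s: float = 13.32
    n_frames: int = 40
    n_baseline: int = 3

    def __post_init__(self) -> None:
        for name in ("tr_ref_ms", "tr_dce_ms", "dt_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("fa_ref_deg", "fa_dce_deg"):
            fa = getattr(self, name)
            if not (0 < fa <= 90):
                raise ValueError(f"{name} must lie in (0, 90] degrees")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if not (1 <= self.n_baseline < self.n_frames):
            raise ValueError("n_baseline must satisfy 1 <= n_baseline < n_frames")

    def frame_times(self) -> np.ndarray:
        """Frame acquisition times in seconds (frame i at i * dt)."""
        return np.arange(self.n_frames) * self.dt_s

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown protocol keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "AcquisitionProtocol":
        """Load from YAML or JSON; a top-level ``protocol`` section is honoured."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if isinstance(data, dict) and "protocol" in data:
            data = data["protocol"]
        return cls.from_dict(data)
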