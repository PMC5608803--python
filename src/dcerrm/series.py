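"""Time-indexed sample containers for dynamic MRI data.

A :class:`DynamicSeries` carries one quantity sampled over time — raw FLASH
signal (arbitrary units), longitudinal relaxation rate R1 (s^-1), relaxation
time T1 (ms) or tracer concentration (mM) — together with a per-sample
validity mask.  Samples can become invalid when the signal-to-T1 inversion
has no solution (e.g. the log argument of the FLASH inversion leaves (0, 1));
the mask propagates through every derived series so that invalid samples are
never silently treated as numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DynamicSeries"]

_SECONDS_PER_MINUTE = 60.0


@dataclass
class DynamicSeries:
    """An ordered set of time-stamped samples with validity flags.

    Parameters
    ----------
    times
        Sampling instants, strictly increasing.  Unit given by ``time_unit``
        ("s" or "min"); seconds are the acquisition-side convention.
    values
        One measured or derived value per instant.  ``unit`` is free-text
        metadata (e.g. "a.u.", "s^-1", "ms", "mM").
    valid
        Boolean mask, True where the sample is usable.  Defaults to all True.
    """

    times: np.ndarray
    values: np.ndarray
    valid: np.ndarray | None = None
    unit: str = ""
    time_unit: str = "s"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.times.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if not (self.times.shape == self.values.shape == self.valid.shape):
            raise ValueError("times, values and valid must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.time_unit not in ("s", "min"):
            raise ValueError(f"unsupported time unit {self.time_unit!r}")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))

    @property
    def all_invalid(self) -> bool:
        return self.n_valid == 0

    def times_min(self) -> np.ndarray:
        """Sampling instants converted to minutes (kinetic time unit)."""
        if self.time_unit == "min":
            return self.times
        return self.times / _SECONDS_PER_MINUTE

    def with_values(self, values: np.ndarray, unit: str | None = None,
                    valid: np.ndarray | None = None) -> "DynamicSeries":
        """A new series on the same grid; validity defaults to this series'."""
        return DynamicSeries(
            times=self.times.copy(),
            values=np.asarray(values, dtype=float),
            valid=self.valid.copy() if valid is None else np.asarray(valid, bool),
            unit=self.unit if unit is None else unit,
            time_unit=self.time_unit,
        )

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]
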