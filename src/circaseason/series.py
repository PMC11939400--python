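"""Minute-resolution actigraphy containers.

An :class:`ActigraphySeries` holds one participant-season wrist recording:
per-minute motor activity (PIM counts), white-light illuminance (lux),
blue-light irradiance (uW/cm^2) and wrist skin temperature (degC), on a
uniform 1-minute local-clock grid, together with a per-minute validity mask.
Local clock time is deliberately kept naive (no UTC conversion): every
endpoint downstream — acrophase, M10 onset, clock-time correlation epochs —
is defined on the local clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEASONS = ("winter", "spring", "summer", "autumn")

#: canonical channel order; activity/light/blue must be non-negative
CHANNELS = ("activity", "light", "blue", "wrist_temp")
NONNEG_CHANNELS = ("activity", "light", "blue")

#: nominal recording length: 7 days of 1-minute epochs
NOMINAL_MINUTES = 7 * 24 * 60


class ActigraphyError(ValueError):
    """Raised for structurally invalid actigraphy input."""


@dataclass
class ActigraphySeries:
    """One participant-season multichannel recording on a 1-min grid.

    Parameters
    ----------
    participant_id : str
    season : str
        One of ``winter``, ``spring``, ``summer``, ``autumn``.
    start : pandas.Timestamp
        Local clock time of the first minute (naive).
    channels : dict of str -> ndarray
        Equal-length float arrays keyed by channel name.  Masked-out
        minutes may hold NaN.
    mask : ndarray of bool
        True where the minute is valid.
    """

    participant_id: str
    season: str
    start: pd.Timestamp
    channels: dict[str, np.ndarray]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ActigraphyError(f"unknown season {self.season!r}")
        if not self.channels:
            raise ActigraphyError("at least one channel required")
        self.start = pd.Timestamp(self.start)
        lengths = {name: len(v) for name, v in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise ActigraphyError(f"channel lengths differ: {lengths}")
        n = next(iter(lengths.values()))
        if n == 0:
            raise ActigraphyError("empty recording")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.mask) != n:
            raise ActigraphyError("mask length mismatch")
        for name in NONNEG_CHANNELS:
            if name in self.channels:
                vals = self.channels[name][self.mask]
                if np.any(vals < 0):
                    raise ActigraphyError(f"negative values in channel {name!r}")

    # ------------------------------------------------------------------
    @property
    def n_minutes(self) -> int:
        return len(self.mask)

    @property
    def is_nominal_length(self) -> bool:
        """Whether the record spans the nominal 7 days (10080 minutes)."""
        return self.n_minutes == NOMINAL_MINUTES

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.n_minutes, freq="min")

    def hours_since_start(self) -> np.ndarray:
        """Elapsed time of each minute in hours from the first sample."""
        return np.arange(self.n_minutes) / 60.0

    def clock_hours(self) -> np.ndarray:
        """Local clock time of each minute in fractional hours [0, 24)."""
        start_h = self.start.hour + self.start.minute / 60.0
        return (start_h + np.arange(self.n_minutes) / 60.0) % 24.0

    def coverage(self) -> float:
        """Fraction of valid minutes."""
        return float(self.mask.mean())

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"no channel {name!r}; have {sorted(self.channels)}")
        return self.channels[name]

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-minute table; masked minutes carry NaN in every channel."""
        data = {"timestamp": self.timestamps}
        for name, vals in self.channels.items():
            out = vals.astype(float).copy()
            out[~self.mask] = np.nan
            data[name] = out
        return pd.DataFrame(data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ActigraphySeries({self.participant_id!r}, {self.season!r}, "
            f"start={self.start}, n={self.n_minutes}, "
            f"coverage={self.coverage():.3f}, channels={sorted(self.channels)})"
        )
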