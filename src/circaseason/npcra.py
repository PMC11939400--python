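"""Non-parametric circadian rhythm analysis (NPCRA).

Classical rest-activity rhythm descriptors computed from binned minute
data (60-minute bins by default):

* IS, inter-daily stability — how reproducible the 24 h profile is across
  days, 0 (noise) to 1 (perfectly repeated waveform);
* IV, intra-daily variability — rhythm fragmentation from the first
  differences of consecutive bins, approaching 0 for a smooth sinusoid and
  2 for white noise;
* M10 / L5 — mean level of the most-active 10 h and least-active 5 h
  cyclic windows of the average day profile, with their onset clock times;
* RA = (M10 - L5) / (M10 + L5), the relative amplitude;
* CFI, circadian function index — equal-weight mean of IS, the inverted
  and normalised IV (clip((2 - IV)/2, 0, 1)) and RA, on a 0-1 scale.

M10/L5 windows are computed on the average day profile (not per day) and
may wrap midnight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

__all__ = ["NonParamMetrics", "NonParametricCircadian", "nonparam_metrics",
           "bin_series", "average_day_profile", "cyclic_window_stats"]

MINUTES_PER_DAY = 1440


@dataclass
class NonParamMetrics:
    IS: float
    IV: float
    M10: float
    M10_onset: float  # clock hours
    L5: float
    L5_onset: float
    RA: float
    CFI: float
    n_bins: int
    flags: tuple[str, ...] = ()


def bin_series(series, channel: str, bin_minutes: int = 60,
               min_bin_coverage: float = 0.8) -> tuple[np.ndarray, np.ndarray]:
    """Bin a channel into consecutive `bin_minutes` means.

    Returns (bin means, bin clock-start hours); bins with fewer than
    `min_bin_coverage` valid minutes are NaN.
    """
    if MINUTES_PER_DAY % bin_minutes:
        raise ValueError("bin width must divide 1440 minutes")
    y = series.channel(channel).astype(float).copy()
    y[~series.mask] = np.nan
    n_bins = series.n_minutes // bin_minutes
    y = y[: n_bins * bin_minutes].reshape(n_bins, bin_minutes)
    counts = np.isfinite(y).sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.nanmean(np.where(np.isfinite(y), y, np.nan), axis=1)
    means[counts < min_bin_coverage * bin_minutes] = np.nan
    start_h = series.start.hour + series.start.minute / 60.0
    starts = (start_h + np.arange(n_bins) * bin_minutes / 60.0) % 24.0
    return means, starts


def average_day_profile(bins: np.ndarray, clock_starts: np.ndarray,
                        bin_minutes: int) -> np.ndarray:
    """Mean value per clock-time-of-day bin, pooling all days (NaN-aware)."""
    p = MINUTES_PER_DAY // bin_minutes
    idx = np.rint(clock_starts * 60.0 / bin_minutes).astype(int) % p
    profile = np.full(p, np.nan)
    for h in range(p):
        vals = bins[idx == h]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            profile[h] = vals.mean()
    return profile


def cyclic_window_stats(profile: np.ndarray, window_bins: int,
                        bin_minutes: int, maximum: bool) -> tuple[float, float]:
    """(mean, onset clock h) of the extreme cyclic moving window.

    Ties are broken by the earliest clock onset.
    """
    p = len(profile)
    ext = np.concatenate([profile, profile[: window_bins - 1]])
    sums = np.convolve(ext, np.ones(window_bins), mode="valid")[:p]
    means = sums / window_bins
    best = int(np.nanargmax(means) if maximum else np.nanargmin(means))
    return float(means[best]), float(best * bin_minutes / 60.0)


def _is_iv(x: np.ndarray, clock_starts: np.ndarray, bin_minutes: int) -> tuple[float, float]:
    """Inter-daily stability and intra-daily variability on binned means.

    IS = [N * sum_h (xbar_h - xbar)^2] / [p * sum_i (x_i - xbar)^2]
    IV = [N * sum_{i>=2} (x_i - x_{i-1})^2] / [(N-1) * sum_i (x_i - xbar)^2]

    computed over the N non-missing bins, with xbar_h the p clock-time bin
    means.  Consecutive differences in IV use adjacent non-missing bins only.
    """
    valid = np.isfinite(x)
    xv = x[valid]
    N = xv.size
    xbar = xv.mean()
    ss = float(np.sum((xv - xbar) ** 2))
    if ss == 0.0:
        return np.nan, np.nan

    p = MINUTES_PER_DAY // bin_minutes
    idx = np.rint(clock_starts * 60.0 / bin_minutes).astype(int) % p
    hour_means = np.full(p, np.nan)
    for h in range(p):
        vals = x[(idx == h) & valid]
        if vals.size:
            hour_means[h] = vals.mean()
    hm = hour_means[np.isfinite(hour_means)]
    IS = float(N * np.sum((hm - xbar) ** 2) / (p * ss))

    pair = valid[1:] & valid[:-1]
    diffs = (x[1:] - x[:-1])[pair]
    IV = float(N * np.sum(diffs**2) / ((N - 1) * ss)) if diffs.size else np.nan
    return IS, IV


class NonParametricCircadian(BaseEstimator):
    """Compute NPCRA metrics for one recording channel.

    Parameters
    ----------
    bin_minutes : int, default 60
        Bin width for IS/IV and the day profile; must divide 1440.
    min_coverage : float, default 0.8
        Minimum overall fraction of valid minutes.

    Attributes (after ``fit``)
    --------------------------
    metrics_ : NonParamMetrics
    IS_, IV_, M10_, L5_, RA_, CFI_ : floats mirroring ``metrics_``.
    """

    def __init__(self, bin_minutes: int = 60, min_coverage: float = 0.8):
        self.bin_minutes = bin_minutes
        self.min_coverage = min_coverage

    def fit(self, series, channel: str = "activity"):
        if series.coverage() < self.min_coverage:
            raise ValueError(
                f"coverage {series.coverage():.2f} below {self.min_coverage}")
        if series.n_minutes < 2 * MINUTES_PER_DAY:
            raise ValueError("NPCRA requires at least 2 full days")
        bins, starts = bin_series(series, channel, self.bin_minutes)
        flags: list[str] = []

        IS, IV = _is_iv(bins, starts, self.bin_minutes)
        if not np.isfinite(IS):
            flags.append("zero_variance")

        profile = average_day_profile(bins, starts, self.bin_minutes)
        p = MINUTES_PER_DAY // self.bin_minutes
        m10, m10_on = cyclic_window_stats(profile, max(1, round(10 * 60 / self.bin_minutes)),
                                          self.bin_minutes, maximum=True)
        l5, l5_on = cyclic_window_stats(profile, max(1, round(5 * 60 / self.bin_minutes)),
                                        self.bin_minutes, maximum=False)
        if m10 + l5 != 0.0:
            ra = (m10 - l5) / (m10 + l5)
        else:
            ra = np.nan
            flags.append("ra_undefined")

        if np.isfinite(IS) and np.isfinite(IV) and np.isfinite(ra):
            cfi = (IS + np.clip((2.0 - IV) / 2.0, 0.0, 1.0) + ra) / 3.0
        else:
            cfi = np.nan

        self.metrics_ = NonParamMetrics(
            IS=IS, IV=IV, M10=m10, M10_onset=m10_on, L5=l5, L5_onset=l5_on,
            RA=float(ra), CFI=float(cfi),
            n_bins=int(np.isfinite(bins).sum()), flags=tuple(flags),
        )
        self.IS_, self.IV_ = IS, IV
        self.M10_, self.L5_, self.RA_, self.CFI_ = m10, l5, float(ra), float(cfi)
        return self


def nonparam_metrics(series, channel: str = "activity",
                     bin_minutes: int = 60) -> NonParamMetrics:
    """IS/IV/M10/L5/RA/CFI for one channel; see :class:`NonParametricCircadian`."""
    return NonParametricCircadian(bin_minutes=bin_minutes).fit(series, channel).metrics_
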