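"""Synthetic Arctic-cohort generator with known ground truth.

Emulates a high-latitude (~66 N) wearable + qPCR study design:

* **Photoperiod** per season drives a smooth raised-cosine daylight
  envelope centred on 12:00 local (solar noon fixed at 12:00; no
  solar-time correction), from a 1 h polar-night window in winter to
  continuous 24 h daylight in summer.
* **Light** = envelope x a per-person time-of-day "habit" profile
  (hourly lognormal factors, constant across the week — people differ in
  when they seek light) x per-minute mean-one lognormal behavioural
  noise, zeroed during the sleep window.  The blue channel is a fixed
  fraction of the white-light curve with its own noise.
* **Activity** = a participant-specific 24 h cosine, hard-gated to
  near-zero during sleep, plus non-negative (exponential) noise;
  **wrist temperature** is a 24 h cosine in antiphase to activity plus
  Gaussian noise.
* **Expression** (log2 relative units) is a linear model on the cohort
  z-scores of the true light MESOR, light acrophase and activity MESOR,
  plus season and native-population offsets and Gaussian noise;
  alternatively expression can be coupled to the mean light in one
  clock window (``coupling="light_window"``) for end-to-end
  peak-localisation experiments.  Quantification cycles are then derived
  so that the 2^-ddCq stage recovers expression exactly up to the
  calibrator convention.

Ground truth for each participant-season (the values the analysis should
recover) is defined as the 24 h cosinor of the *expected* (noise-free)
minute curve, which is exactly what the estimators converge to.

One RNG stream is derived from the master seed per participant-season,
so subsetting the cohort never changes other participants' data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .series import ActigraphySeries, SEASONS

__all__ = ["GeneratorConfig", "SyntheticCohort", "daylight_envelope",
           "simulate_recording", "simulate_expression", "simulate_cohort"]

MINUTES_PER_DAY = 1440

_SEASON_START = {          # first minute of each 7-day recording week
    "winter": "2023-12-18T00:00:00",
    "spring": "2024-03-18T00:00:00",
    "summer": "2024-06-17T00:00:00",
    "autumn": "2024-09-16T00:00:00",
}
# stream-purpose tags for per-entity RNG substreams
_S_RECORD, _S_EXPR, _S_TRAITS, _S_META, _S_AVAIL = 11, 13, 17, 19, 23


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions.

    Seasonal participation reproduces a 29/22/25/21 winter/spring/summer/
    autumn availability pattern; 27.6% of participants are Arctic natives.
    """

    n_participants: int = 29
    fraction_native: float = 0.276
    #: per-season participation probability (winter complete)
    availability: dict = field(default_factory=lambda: {
        "winter": 1.0, "spring": 22 / 29, "summer": 25 / 29, "autumn": 21 / 29})
    #: daylight hours per season at the study latitude
    photoperiod_h: dict = field(default_factory=lambda: {
        "winter": 1.0, "spring": 12.0, "summer": 24.0, "autumn": 12.0})
    days: int = 7

    # activity model (PIM counts)
    activity_mesor: float = 150.0
    activity_mesor_sd: float = 25.0
    activity_amplitude: float = 120.0
    activity_amplitude_sd: float = 20.0
    activity_acrophase: float = 15.0        # clock h
    activity_acrophase_sd: float = 0.75
    activity_noise_mean: float = 10.0       # exponential additive noise, counts
    #: per-season sleep window (start clock h, end clock h), may wrap midnight
    sleep_window: dict = field(default_factory=lambda: {
        s: (23.0, 7.0) for s in SEASONS})

    # light model
    peak_lux: float = 1000.0
    night_light_lux: float = 0.5            # indoor/leakage baseline, all minutes
    light_noise_sd: float = 0.5             # per-minute lognormal sigma (log scale)
    habit_sd: float = 0.35                  # hourly time-of-day lognormal sigma
    phase_jitter_sd: float = 0.25           # h; spread of the envelope centre
    blue_fraction: float = 0.02             # uW/cm^2 per lux
    blue_noise_sd: float = 0.5

    # wrist temperature model (degC)
    temp_mesor: float = 34.0
    temp_amplitude: float = 1.0
    temp_noise_sd: float = 0.3

    # expression model, log2 relative units
    coupling: str = "endpoints"             # or "light_window"
    b0: float = 0.0
    b_season: dict = field(default_factory=lambda: {
        "winter": -0.4, "spring": 0.0, "summer": 0.5, "autumn": 0.2})
    b_native: float = 0.3
    b_light_mesor: float = 0.35
    b_light_phase: float = 0.25
    b_activity_mesor: float = 0.25
    residual_sd: float = 0.6
    coupling_window: tuple = (16.0, 20.0)   # clock h, light_window mode
    b_window: float = 0.8
    window_residual_sd: float = 0.5

    # qPCR model
    cq_reference_mean: float = 20.0
    cq_reference_sd: float = 0.5
    calibration_constant: float = 3.0       # dCq of a sample with log2 RE = 0

    def __post_init__(self) -> None:
        for s, p in self.availability.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"availability[{s}]={p} outside [0,1]")
        for s, h in self.photoperiod_h.items():
            if not 0.0 <= h <= 24.0:
                raise ValueError(f"photoperiod_h[{s}]={h} outside [0,24]")
        if not 0.0 <= self.fraction_native <= 1.0:
            raise ValueError("fraction_native outside [0,1]")
        for name in ("activity_mesor_sd", "activity_amplitude_sd",
                     "activity_acrophase_sd", "light_noise_sd", "habit_sd",
                     "phase_jitter_sd", "blue_noise_sd", "temp_noise_sd",
                     "residual_sd", "window_residual_sd", "cq_reference_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def season_counts(self) -> dict[str, int]:
        """Deterministic per-season participant counts."""
        return {s: int(round(self.availability[s] * self.n_participants))
                for s in SEASONS}

    def replace(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        kw = dict(d)
        if "coupling_window" in kw:
            kw["coupling_window"] = tuple(kw["coupling_window"])
        if "sleep_window" in kw:
            kw["sleep_window"] = {s: tuple(w) if w is not None else None
                                  for s, w in kw["sleep_window"].items()}
        return cls(**kw)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _circdist(a: np.ndarray, b: float, period: float = 24.0) -> np.ndarray:
    d = np.abs((a - b) % period)
    return np.minimum(d, period - d)


def daylight_envelope(clock_h: np.ndarray, photoperiod: float,
                      peak: float, center: float = 12.0) -> np.ndarray:
    """Raised-cosine daylight window of width `photoperiod` hours.

    envelope(t) = peak * 0.5 * (1 + cos(2*pi*(t - center)/photoperiod))
    inside |t - center| <= photoperiod/2 (circularly), 0 outside.
    The 24 h mean is peak * photoperiod / 48, strictly increasing in
    photoperiod.
    """
    if not 0.0 <= photoperiod <= 24.0:
        raise ValueError(f"photoperiod {photoperiod} outside [0,24]")
    d = _circdist(np.asarray(clock_h, dtype=float), center)
    env = np.zeros_like(d)
    if photoperiod > 0:
        inside = d <= photoperiod / 2.0
        env[inside] = peak * 0.5 * (1.0 + np.cos(2 * np.pi * d[inside] / photoperiod))
    return env


def _sleep_gate(clock_h: np.ndarray, window: tuple[float, float] | None) -> np.ndarray:
    """1 awake / 0 asleep; the window may wrap midnight."""
    if window is None:
        return np.ones_like(clock_h)
    s, e = window
    if s == e:
        return np.ones_like(clock_h)
    if s < e:
        asleep = (clock_h >= s) & (clock_h < e)
    else:
        asleep = (clock_h >= s) | (clock_h < e)
    return (~asleep).astype(float)


def _mean_one_lognormal(rng: np.random.Generator, sd: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with expectation exactly 1."""
    if sd == 0:
        return np.ones(size)
    return rng.lognormal(mean=-0.5 * sd * sd, sigma=sd, size=size)


# cached cosinor projector on the canonical 1440-minute day grid
_DAY_CLOCK_H = np.arange(MINUTES_PER_DAY) / 60.0
_DAY_DESIGN = np.column_stack([
    np.ones(MINUTES_PER_DAY),
    np.cos(2 * np.pi * _DAY_CLOCK_H / 24.0),
    np.sin(2 * np.pi * _DAY_CLOCK_H / 24.0),
])
_DAY_PINV = np.linalg.pinv(_DAY_DESIGN)


def _day_cosinor(day_curve: np.ndarray) -> tuple[float, float, float]:
    """(mesor, amplitude, acrophase h) of the 24 h cosinor of a day curve."""
    m, b, g = _DAY_PINV @ day_curve
    amp = float(np.hypot(b, g))
    phi = float((np.arctan2(g, b) * 24.0 / (2 * np.pi)) % 24.0)
    return float(m), amp, phi


def participant_traits(config: GeneratorConfig, seed: int, pidx: int) -> dict:
    """Stable per-participant activity rhythm parameters."""
    rng = _rng(seed, pidx, _S_TRAITS)
    return {
        "act_mesor": max(1.0, rng.normal(config.activity_mesor, config.activity_mesor_sd)),
        "act_amplitude": max(0.0, rng.normal(config.activity_amplitude,
                                             config.activity_amplitude_sd)),
        "act_acrophase": rng.normal(config.activity_acrophase,
                                    config.activity_acrophase_sd) % 24.0,
    }


def _expected_day_curves(config: GeneratorConfig, season: str, traits: dict,
                         phase_shift: float, habit: np.ndarray) -> dict[str, np.ndarray]:
    """Noise-free expected minute curves over one 24 h day."""
    tc = _DAY_CLOCK_H
    gate = _sleep_gate(tc, config.sleep_window.get(season))
    env = daylight_envelope(tc, config.photoperiod_h[season], config.peak_lux,
                            center=12.0 + phase_shift)
    habit_min = np.repeat(habit, 60)
    # daylight gated by sleep, plus an ungated indoor/leakage baseline so
    # night epochs carry (weak, uninformative) variance as in real records
    light = env * habit_min * gate + config.night_light_lux
    act_cos = traits["act_mesor"] + traits["act_amplitude"] * np.cos(
        2 * np.pi * (tc - traits["act_acrophase"]) / 24.0)
    act_base = np.maximum(act_cos, 0.0) * gate
    noise_scale = np.where(gate > 0, 1.0, 0.2)  # residual tossing during sleep
    activity = act_base + config.activity_noise_mean * noise_scale
    temp = config.temp_mesor + config.temp_amplitude * np.cos(
        2 * np.pi * (tc - (traits["act_acrophase"] + 12.0)) / 24.0)
    return {"light": light, "activity": activity, "activity_base": act_base,
            "noise_scale": noise_scale, "wrist_temp": temp, "gate": gate}


def simulate_recording(config: GeneratorConfig, seed: int, pidx: int, season: str,
                       traits: dict | None = None,
                       channels=("activity", "light", "blue", "wrist_temp"),
                       ) -> tuple[ActigraphySeries, dict]:
    """Simulate one 7-day participant-season recording.

    Returns the series plus its ground-truth row (true 24 h cosinor
    parameters of the expected light and activity curves, sleep window and
    the expected mean light inside the expression-coupling window).
    Restricting `channels` skips the unneeded noise draws.
    """
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}")
    traits = traits or participant_traits(config, seed, pidx)
    sidx = SEASONS.index(season)
    # independent substream per channel, so restricting `channels` leaves
    # the generated values of the remaining channels unchanged
    base_rng = _rng(seed, pidx, sidx, _S_RECORD, 0)
    phase_shift = base_rng.normal(0.0, config.phase_jitter_sd)
    log_habit = base_rng.normal(0.0, config.habit_sd, size=24)
    habit = np.exp(log_habit - 0.5 * config.habit_sd**2)

    day = _expected_day_curves(config, season, traits, phase_shift, habit)
    n = config.days * MINUTES_PER_DAY
    idx = np.arange(n) % MINUTES_PER_DAY        # recordings start at 00:00

    out: dict[str, np.ndarray] = {}
    if "light" in channels or "blue" in channels:
        base_light = day["light"][idx]
        if "light" in channels:
            rng = _rng(seed, pidx, sidx, _S_RECORD, 1)
            out["light"] = base_light * _mean_one_lognormal(rng, config.light_noise_sd, n)
        if "blue" in channels:
            rng = _rng(seed, pidx, sidx, _S_RECORD, 2)
            out["blue"] = (config.blue_fraction * base_light
                           * _mean_one_lognormal(rng, config.blue_noise_sd, n))
    if "activity" in channels:
        rng = _rng(seed, pidx, sidx, _S_RECORD, 3)
        if config.activity_noise_mean > 0:
            eps = rng.exponential(config.activity_noise_mean, size=n)
        else:
            eps = np.zeros(n)
        out["activity"] = day["activity_base"][idx] + eps * day["noise_scale"][idx]
    if "wrist_temp" in channels:
        rng = _rng(seed, pidx, sidx, _S_RECORD, 4)
        out["wrist_temp"] = day["wrist_temp"][idx] + rng.normal(
            0.0, config.temp_noise_sd, size=n)

    pid = f"P{pidx + 1:02d}"
    series = None
    if out:
        series = ActigraphySeries(participant_id=pid, season=season,
                                  start=pd.Timestamp(_SEASON_START[season]),
                                  channels=out)

    lm, la, lph = _day_cosinor(day["light"])
    am, aa, aph = _day_cosinor(day["activity"])
    w0, w1 = config.coupling_window
    in_window = (_DAY_CLOCK_H >= w0) & (_DAY_CLOCK_H < w1)
    truth = {
        "participant_id": pid, "season": season,
        "light_mesor": lm, "light_amplitude": la, "light_acrophase": lph,
        "activity_mesor": am, "activity_amplitude": aa, "activity_acrophase": aph,
        "sleep_start": (config.sleep_window.get(season) or (np.nan, np.nan))[0],
        "sleep_end": (config.sleep_window.get(season) or (np.nan, np.nan))[1],
        "window_light": float(day["light"][in_window].mean()) if in_window.any() else np.nan,
    }
    return series, truth


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_expression(config: GeneratorConfig, truth: pd.DataFrame,
                        native: dict[str, bool], seed: int) -> pd.DataFrame:
    """Generate log2 expression and quantification cycles from truth rows.

    In ``endpoints`` mode the linear predictor combines season and
    population offsets with the cohort z-scores of true light MESOR,
    light acrophase and activity MESOR; in ``light_window`` mode it is
    ``b_window`` times the z-score of expected light inside the coupling
    window.  Cq values are constructed so the 2^-ddCq stage inverts them
    exactly: cq_target = cq_reference + (calibration constant - log2 RE).
    """
    if truth.empty:
        raise ValueError("no truth rows to generate expression from")
    t = truth.reset_index(drop=True).copy()
    is_native = t["participant_id"].map(native).astype(float).to_numpy()

    if config.coupling == "light_window":
        z_w = _zscore(t["window_light"].to_numpy(float))
        lin = config.b0 + config.b_window * z_w
        t["contrib_window"] = config.b_window * z_w
        resid_sd = config.window_residual_sd
    elif config.coupling == "endpoints":
        z_lm = _zscore(t["light_mesor"].to_numpy(float))
        z_lp = _zscore(t["light_acrophase"].to_numpy(float))
        z_am = _zscore(t["activity_mesor"].to_numpy(float))
        season_off = t["season"].map(config.b_season).to_numpy(float)
        lin = (config.b0 + season_off + config.b_native * is_native
               + config.b_light_mesor * z_lm
               + config.b_light_phase * z_lp
               + config.b_activity_mesor * z_am)
        t["contrib_season"] = season_off
        t["contrib_native"] = config.b_native * is_native
        t["contrib_light_mesor"] = config.b_light_mesor * z_lm
        t["contrib_light_phase"] = config.b_light_phase * z_lp
        t["contrib_activity_mesor"] = config.b_activity_mesor * z_am
        resid_sd = config.residual_sd
    else:
        raise ValueError(f"unknown coupling mode {config.coupling!r}")

    rows = []
    log2_re = np.empty(len(t))
    for i, row in t.iterrows():
        pidx = int(row["participant_id"][1:]) - 1
        rng = _rng(seed, pidx, SEASONS.index(row["season"]), _S_EXPR)
        eps = rng.normal(0.0, resid_sd) if resid_sd > 0 else 0.0
        log2_re[i] = lin[i] + eps
        cq_ref = rng.normal(config.cq_reference_mean, config.cq_reference_sd)
        rows.append({
            "participant_id": row["participant_id"], "season": row["season"],
            "cq_target": cq_ref + config.calibration_constant - log2_re[i],
            "cq_reference": cq_ref,
            "sample_time": "08:00",
        })
    t["log2_re"] = log2_re
    truth["log2_re"] = log2_re  # annotate caller's frame too
    expr = pd.DataFrame(rows)
    expr.attrs["log2_re"] = log2_re
    return expr


@dataclass
class SyntheticCohort:
    """Everything one simulated cohort produces."""

    config: GeneratorConfig
    seed: int
    recordings: dict            # (participant_id, season) -> ActigraphySeries
    truth: pd.DataFrame         # per participant-season ground truth
    expression: pd.DataFrame    # qPCR table
    meta: pd.DataFrame          # participant metadata


def _metadata(config: GeneratorConfig, seed: int) -> pd.DataFrame:
    rng = _rng(seed, _S_META)
    n = config.n_participants
    n_native = int(round(config.fraction_native * n))
    native_idx = set(rng.permutation(n)[:n_native].tolist())
    rows = []
    for i in range(n):
        rows.append({
            "participant_id": f"P{i + 1:02d}",
            "age": float(np.clip(rng.normal(40.0, 10.0), 18.0, 70.0)),
            "sex": "F" if rng.random() < 0.5 else "M",
            "bmi": float(np.clip(rng.normal(26.0, 4.0), 17.0, 45.0)),
            "population": "native" if i in native_idx else "nonnative",
        })
    return pd.DataFrame(rows)


def _season_rosters(config: GeneratorConfig, seed: int) -> dict[str, np.ndarray]:
    """Deterministic per-season participant subsets of the target sizes."""
    counts = config.season_counts()
    rosters = {}
    for s in SEASONS:
        rng = _rng(seed, SEASONS.index(s), _S_AVAIL)
        rosters[s] = np.sort(rng.choice(config.n_participants, size=counts[s],
                                        replace=False))
    return rosters


def simulate_cohort(config: GeneratorConfig | None = None, seed: int = 0,
                    channels=("activity", "light", "blue", "wrist_temp"),
                    keep_recordings: bool = True) -> SyntheticCohort:
    """Simulate the full cohort: recordings, ground truth, qPCR table, metadata.

    Identical (config, seed) reproduce the cohort bit-identically.
    ``keep_recordings=False`` discards the minute-level series after the
    truth rows are computed (Monte-Carlo loops that only need truth).
    """
    config = config or GeneratorConfig()
    meta = _metadata(config, seed)
    native = dict(zip(meta["participant_id"], meta["population"] == "native"))
    rosters = _season_rosters(config, seed)

    recordings: dict = {}
    truth_rows = []
    traits_cache = {i: participant_traits(config, seed, i)
                    for i in range(config.n_participants)}
    for season in SEASONS:
        for pidx in rosters[season]:
            series, truth = simulate_recording(config, seed, int(pidx), season,
                                               traits=traits_cache[int(pidx)],
                                               channels=channels)
            if keep_recordings and series is not None:
                recordings[(series.participant_id, season)] = series
            truth_rows.append(truth)
    truth = pd.DataFrame(truth_rows)
    expression = simulate_expression(config, truth, native, seed)
    return SyntheticCohort(config=config, seed=seed, recordings=recordings,
                           truth=truth, expression=expression, meta=meta)
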