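"""End-to-end orchestration: recordings -> endpoints -> cohort table -> models.

This module glues the stages together the way the seasonal-expression
analysis runs them: qPCR quantification, per-recording cosinor and
non-parametric endpoints, cohort assembly, the clock-time correlation map
and the sigma-restricted GLMs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cosinor import actigraphy_endpoints
from .corrmap import correlation_map, epoch_profile, fit_peak_model
from .io import assemble_cohort
from .npcra import nonparam_metrics
from .qpcr import delta_delta_cq

__all__ = ["recording_endpoints", "derive_metric_table", "build_cohort",
           "profile_matrix", "run_correlation_analysis"]

#: channels given parametric (cosinor) endpoints, per the study design
COSINOR_CHANNELS = ("activity", "light", "blue", "wrist_temp")
#: channels given non-parametric endpoints
NPCRA_CHANNELS = ("activity", "blue")


def recording_endpoints(series, cosinor_channels=COSINOR_CHANNELS,
                        npcra_channels=NPCRA_CHANNELS,
                        bin_minutes: int = 60) -> dict:
    """One flat row of derived endpoints for a recording.

    Cosinor endpoints are named ``<channel>_mesor`` / ``_amplitude`` /
    ``_acrophase``; non-parametric ones ``<channel>_is`` / ``_iv`` /
    ``_m10`` / ``_l5`` / ``_ra`` / ``_cfi``.
    """
    row: dict = {"participant_id": series.participant_id, "season": series.season}
    for ch in cosinor_channels:
        if ch not in series.channels:
            continue
        fit = actigraphy_endpoints(series, ch)
        if fit is None:
            continue
        row[f"{ch}_mesor"] = fit.mesor
        row[f"{ch}_amplitude"] = fit.amplitude
        row[f"{ch}_acrophase"] = fit.acrophase
    for ch in npcra_channels:
        if ch not in series.channels:
            continue
        m = nonparam_metrics(series, ch, bin_minutes=bin_minutes)
        row.update({f"{ch}_is": m.IS, f"{ch}_iv": m.IV, f"{ch}_m10": m.M10,
                    f"{ch}_m10_onset": m.M10_onset, f"{ch}_l5": m.L5,
                    f"{ch}_l5_onset": m.L5_onset, f"{ch}_ra": m.RA,
                    f"{ch}_cfi": m.CFI})
    return row


def derive_metric_table(recordings, **kw) -> pd.DataFrame:
    """Endpoint rows for an iterable (or dict) of recordings."""
    if isinstance(recordings, dict):
        recordings = recordings.values()
    return pd.DataFrame([recording_endpoints(s, **kw) for s in recordings])


def build_cohort(expression: pd.DataFrame, meta: pd.DataFrame,
                 recordings=None, calibrator="winter",
                 metrics: pd.DataFrame | None = None, **kw) -> pd.DataFrame:
    """qPCR quantification + endpoint derivation + cohort assembly.

    Returns one row per (participant, season) with ``relative_expression``,
    ``log2_re`` and every derived endpoint; missing stages stay NaN.
    """
    expr = delta_delta_cq(expression, calibrator=calibrator)
    if metrics is None and recordings is not None:
        metrics = derive_metric_table(recordings, **kw)
    cohort = assemble_cohort(expr, meta, metrics)
    with np.errstate(divide="ignore"):
        cohort["log2_re"] = np.log2(cohort["relative_expression"])
    return cohort


def profile_matrix(recordings, keys, channel: str = "light",
                   width: int = 30) -> np.ndarray:
    """Stack per-recording clock-epoch profiles for the given keys.

    `keys` is a sequence of (participant_id, season) pairs aligned with the
    expression vector; missing recordings produce all-NaN rows.
    """
    n_epochs = 1440 // width
    rows = []
    for key in keys:
        series = recordings.get(tuple(key)) if isinstance(recordings, dict) else None
        if series is None or channel not in series.channels:
            rows.append(np.full(n_epochs, np.nan))
        else:
            rows.append(epoch_profile(series, channel, width=width))
    return np.vstack(rows)


def run_correlation_analysis(cohort: pd.DataFrame, recordings,
                             channel: str = "light", width: int = 30,
                             q: float = 0.1, periods=(24.0, 12.0)):
    """Clock-time correlation map + harmonic peak model for one channel.

    Pools all participant-season observations with both a recording and an
    expression value into a single FDR family.
    """
    ok = cohort["relative_expression"].notna()
    sub = cohort[ok]
    profiles = profile_matrix(recordings, sub[["participant_id", "season"]].to_numpy(),
                              channel=channel, width=width)
    cmap = correlation_map(profiles, sub["relative_expression"].to_numpy(float),
                           q=q, width=width, channel=channel)
    model = fit_peak_model(cmap, periods=periods)
    return cmap, model
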