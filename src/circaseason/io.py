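"""CSV readers/writers and cohort-table assembly.

File dialect: comma separated, ISO-8601 timestamps, ``.`` decimal separator.
Column names follow the default mapping below but can be remapped for other
device exports.  Actigraphy minutes missing from a file are re-inserted on
read with the validity mask cleared, never imputed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .series import ActigraphyError, ActigraphySeries, SEASONS

log = logging.getLogger(__name__)

#: CSV column -> internal channel name
DEFAULT_COLUMNS = {
    "pim": "activity",
    "lux": "light",
    "blue_uw_cm2": "blue",
    "wrist_temp_c": "wrist_temp",
}
_REVERSE_COLUMNS = {v: k for k, v in DEFAULT_COLUMNS.items()}

EXPRESSION_COLUMNS = ["participant_id", "season", "cq_target", "cq_reference"]
META_COLUMNS = ["participant_id", "age", "sex", "bmi", "population"]


def read_actigraphy(
    path,
    participant_id: str = "",
    season: str = "winter",
    columns: dict[str, str] | None = None,
) -> ActigraphySeries:
    """Read a per-minute actigraphy CSV into an :class:`ActigraphySeries`.

    The file must have a ``timestamp`` column and at least one channel
    column.  Rows are sorted by time; gaps in the minute grid are filled
    with masked (invalid) minutes; non-numeric or negative-count cells
    invalidate that minute with a logged warning.  Duplicate timestamps
    and empty files are hard errors.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    raw = pd.read_csv(path, float_precision="round_trip")
    if raw.empty:
        raise ActigraphyError(f"{path}: empty actigraphy file")
    if "timestamp" not in raw.columns:
        raise ActigraphyError(f"{path}: no 'timestamp' column")
    raw["timestamp"] = pd.to_datetime(raw["timestamp"])
    raw = raw.sort_values("timestamp")
    if raw["timestamp"].duplicated().any():
        dup = raw.loc[raw["timestamp"].duplicated(), "timestamp"].iloc[0]
        raise ActigraphyError(f"{path}: duplicate timestamp {dup}")

    present = [c for c in raw.columns if c in colmap]
    if not present:
        raise ActigraphyError(f"{path}: no recognised channel columns")

    grid = pd.date_range(raw["timestamp"].iloc[0], raw["timestamp"].iloc[-1], freq="min")
    frame = raw.set_index("timestamp").reindex(grid)

    channels: dict[str, np.ndarray] = {}
    bad = np.zeros(len(grid), dtype=bool)
    for col in present:
        vals = pd.to_numeric(frame[col], errors="coerce").to_numpy(dtype=float)
        nonnum = frame[col].notna().to_numpy() & np.isnan(vals)
        if nonnum.any():
            log.warning("%s: %d non-numeric values in %r masked", path, nonnum.sum(), col)
        name = colmap[col]
        if name in ("activity", "light", "blue"):
            neg = vals < 0
            if neg.any():
                log.warning("%s: %d negative values in %r masked", path, neg.sum(), col)
                vals = np.where(neg, np.nan, vals)
        channels[name] = vals

    mask = np.ones(len(grid), dtype=bool)
    for vals in channels.values():
        mask &= np.isfinite(vals)
    mask &= ~bad
    n_gap = int((~frame[present[0]].index.isin(raw["timestamp"])).sum())
    if n_gap:
        log.info("%s: %d missing minutes masked", path, n_gap)
    return ActigraphySeries(
        participant_id=participant_id,
        season=season,
        start=grid[0],
        channels=channels,
        mask=mask,
    )


def write_actigraphy(series: ActigraphySeries, path) -> None:
    """Write a series as CSV; masked minutes get empty channel cells.

    Floats are written with ``repr`` round-trip precision so that
    write-then-read reproduces finite values bit-identically.
    """
    frame = series.to_frame().rename(columns=_REVERSE_COLUMNS)
    frame["timestamp"] = frame["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    frame.to_csv(path, index=False, float_format="%.17g")


def read_expression(path) -> pd.DataFrame:
    """Read a qPCR table (participant_id, season, cq_target, cq_reference)."""
    df = pd.read_csv(path)
    missing = set(EXPRESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing expression columns {sorted(missing)}")
    bad = ~df["season"].isin(SEASONS)
    if bad.any():
        raise ValueError(f"{path}: unknown seasons {sorted(df.loc[bad, 'season'].unique())}")
    return df


def read_metadata(path) -> pd.DataFrame:
    """Read participant metadata (age, sex, bmi, population)."""
    df = pd.read_csv(path)
    missing = set(META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    if (df["age"] <= 0).any() or (df["bmi"] <= 0).any():
        raise ValueError(f"{path}: age and bmi must be positive")
    if df["participant_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate participant_id rows")
    return df


def assemble_cohort(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    metrics: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join expression, metadata and derived recording metrics.

    Outer join on ``(participant_id, season)``: one row per distinct pair
    present in either the expression table or the metrics table, with
    metadata broadcast per participant.  Absent cells stay NaN — partially
    observed seasons are representable, never dropped.

    Raises
    ------
    ValueError
        If an expression row has no metadata, or duplicate
        (participant, season) keys conflict.
    """
    key = ["participant_id", "season"]
    for name, df in [("expression", expr), ("metrics", metrics)]:
        if df is not None and df.duplicated(subset=key).any():
            raise ValueError(f"duplicate (participant_id, season) rows in {name} table")
    known = set(meta["participant_id"])
    orphans = set(expr["participant_id"]) - known
    if orphans:
        raise ValueError(f"expression rows with no metadata: {sorted(orphans)}")

    table = expr.copy()
    if metrics is not None and len(metrics):
        stray = set(metrics["participant_id"]) - known
        if stray:
            raise ValueError(f"metric rows with no metadata: {sorted(stray)}")
        table = table.merge(metrics, on=key, how="outer")
    table = table.merge(meta, on="participant_id", how="left", validate="many_to_one")
    order = {s: i for i, s in enumerate(SEASONS)}
    table = table.sort_values(key, key=lambda s: s.map(order) if s.name == "season" else s)
    return table.reset_index(drop=True)
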