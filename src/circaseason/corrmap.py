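"""Clock-time windowed correlation mapping between a wearable channel and
gene expression.

The procedure: average a channel (light or activity) in consecutive
30-minute clock-time epochs pooled over the whole recording (48 epochs per
24 h day), correlate each epoch's mean across participant-season
observations with relative expression (Pearson), control the 48 tests at
FDR q = 0.1 by Benjamini-Hochberg, and approximate the correlation-vs-
clock-time profile with a multi-component harmonic (cosinor) model whose
fitted local maxima locate the clock windows where the channel best
predicts expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .cosinor import CosinorFit, fit_cosinor

log = logging.getLogger(__name__)

__all__ = ["CorrelationMap", "HarmonicPeakModel", "CorrelationMapper",
           "epoch_profile", "correlation_map", "fit_peak_model", "flag_outliers"]

MINUTES_PER_DAY = 1440


def epoch_profile(series, channel: str, width: int = 30,
                  min_coverage: float = 0.8) -> np.ndarray:
    """Mean channel value per consecutive clock-time epoch of `width` minutes.

    All days of the recording are pooled: entry ``e`` is the mean over every
    valid minute whose clock time falls in epoch ``e``.  Epochs whose valid-
    minute coverage over the record falls below `min_coverage` are NaN.
    """
    if MINUTES_PER_DAY % width:
        raise ValueError("epoch width must divide 1440 minutes")
    n_epochs = MINUTES_PER_DAY // width
    y = series.channel(channel).astype(float).copy()
    y[~series.mask] = np.nan
    start_min = series.start.hour * 60 + series.start.minute
    clock_min = (start_min + np.arange(series.n_minutes)) % MINUTES_PER_DAY
    epoch = clock_min // width

    valid = np.isfinite(y)
    slots = np.bincount(epoch, minlength=n_epochs).astype(float)
    counts = np.bincount(epoch[valid], minlength=n_epochs).astype(float)
    sums = np.bincount(epoch[valid], weights=y[valid], minlength=n_epochs)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[(slots == 0) | (counts < min_coverage * slots)] = np.nan
    return out


@dataclass
class CorrelationMap:
    """48 epoch-wise correlations with FDR flags."""

    epochs: pd.DataFrame   # columns: start_h, end_h, midpoint_h, r, n, p, significant
    fdr_level: float
    channel: str
    n_undefined: int = 0

    @property
    def r(self) -> np.ndarray:
        return self.epochs["r"].to_numpy()

    @property
    def midpoints(self) -> np.ndarray:
        return self.epochs["midpoint_h"].to_numpy()


@dataclass
class HarmonicPeakModel:
    """Harmonic approximation of the correlation-vs-clock-time profile."""

    fit: CosinorFit
    peaks: list[tuple[float, float]] = field(default_factory=list)  # (clock h, fitted r), major first
    degenerate: bool = False
    alt_12h_fit: "HarmonicPeakModel | None" = None  # 12 h-only refit when 24 h amp not significant

    @property
    def major_peak(self) -> tuple[float, float] | None:
        return self.peaks[0] if self.peaks else None


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        return np.nan, n, np.nan
    xv, yv = x[ok], y[ok]
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return np.nan, n, np.nan
    r = float(np.corrcoef(xv, yv)[0, 1])
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        return r, n, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return r, n, p


class CorrelationMapper(BaseEstimator):
    """Epoch-wise expression-channel correlation with BH-FDR control.

    Parameters
    ----------
    width : int, default 30
        Epoch width in minutes (must divide 1440; 30 gives 48 epochs).
    q : float, default 0.1
        Benjamini-Hochberg FDR level over the epoch family.
    method : {"pearson", "spearman"}
        Spearman is offered for sensitivity analyses only.

    ``fit`` takes a (n_observations, n_epochs) profile matrix (one row per
    participant-season) and the matching expression vector.  Epochs where
    r is undefined (zero variance or n < 3) are excluded from the FDR
    family with a logged count.

    Attributes
    ----------
    map_ : CorrelationMap
    """

    def __init__(self, width: int = 30, q: float = 0.1, method: str = "pearson",
                 channel: str = "light"):
        self.width = width
        self.q = q
        self.method = method
        self.channel = channel

    def fit(self, profiles, expression):
        profiles = np.asarray(profiles, dtype=float)
        expression = np.asarray(expression, dtype=float).ravel()
        if profiles.ndim != 2 or profiles.shape[0] != expression.size:
            raise ValueError("profiles must be (n_obs, n_epochs) matching expression")
        if MINUTES_PER_DAY % self.width:
            raise ValueError("epoch width must divide 1440 minutes")
        n_epochs = MINUTES_PER_DAY // self.width
        if profiles.shape[1] != n_epochs:
            raise ValueError(f"expected {n_epochs} epochs, got {profiles.shape[1]}")

        rows = []
        for e in range(n_epochs):
            x = profiles[:, e]
            if self.method == "spearman":
                ok = np.isfinite(x) & np.isfinite(expression)
                if ok.sum() >= 3 and np.ptp(x[ok]) > 0 and np.ptp(expression[ok]) > 0:
                    r, p = stats.spearmanr(x[ok], expression[ok])
                    r, n, p = float(r), int(ok.sum()), float(p)
                else:
                    r, n, p = np.nan, int(ok.sum()), np.nan
            else:
                r, n, p = _pearson_with_p(x, expression)
            rows.append({
                "start_h": e * self.width / 60.0,
                "end_h": (e + 1) * self.width / 60.0,
                "midpoint_h": (e + 0.5) * self.width / 60.0,
                "r": r, "n": n, "p": p,
            })
        table = pd.DataFrame(rows)

        defined = np.isfinite(table["p"].to_numpy())
        n_undef = int((~defined).sum())
        if n_undef:
            log.warning("%d epoch(s) with undefined correlation dropped from FDR family",
                        n_undef)
        significant = np.zeros(n_epochs, dtype=bool)
        if defined.any():
            reject, *_ = multipletests(table.loc[defined, "p"], alpha=self.q,
                                       method="fdr_bh")
            significant[defined] = reject
        table["significant"] = significant

        self.map_ = CorrelationMap(epochs=table, fdr_level=self.q,
                                   channel=self.channel, n_undefined=n_undef)
        return self


def correlation_map(profiles, expression, q: float = 0.1, width: int = 30,
                    channel: str = "light", method: str = "pearson") -> CorrelationMap:
    """Epoch-wise Pearson correlation map; see :class:`CorrelationMapper`.

    `profiles` is an (n_observations, n_epochs) matrix of per participant-
    season epoch means (from :func:`epoch_profile`); `expression` the
    matching relative-expression vector.  Observations are pooled across
    seasons by default; pass per-season subsets for within-season maps.
    """
    return CorrelationMapper(width=width, q=q, method=method,
                             channel=channel).fit(profiles, expression).map_


def fit_peak_model(cmap: CorrelationMap, periods=(24.0, 12.0)) -> HarmonicPeakModel:
    """Fit a harmonic model to the (epoch midpoint, r) profile and find peaks.

    Peaks are the local maxima of the fitted curve on a 1-minute clock grid,
    ordered by fitted height (major first).  When the 24 h component's
    amplitude CI covers zero, a 12 h-only refit is attached
    (``alt_12h_fit``), mirroring the bimodal-only structure seen for
    activity profiles.
    """
    ok = np.isfinite(cmap.r)
    if ok.sum() < 2 * len(periods) + 2:
        raise ValueError("too few defined epochs for the harmonic model")
    try:
        fit = fit_cosinor(cmap.midpoints[ok], cmap.r[ok], periods=periods)
    except np.linalg.LinAlgError:
        return HarmonicPeakModel(fit=None, degenerate=True)  # type: ignore[arg-type]

    peaks: list[tuple[float, float]] = []
    # a perfect (zero-residual) fit counts as rhythmic, p is just flagged
    if fit.degenerate or fit.p_value <= 0.05:
        heights = fit.predict(np.asarray(fit.peak_times))
        order = np.argsort(-heights)
        peaks = [(fit.peak_times[i], float(heights[i])) for i in order]

    model = HarmonicPeakModel(fit=fit, peaks=peaks)
    if len(periods) > 1:
        comp24 = next((c for c in fit.components if abs(c.period - 24.0) < 1e-9), None)
        if comp24 is not None and not comp24.amplitude_significant:
            rest = tuple(p for p in periods if abs(p - 24.0) >= 1e-9)
            if rest:
                model.alt_12h_fit = fit_peak_model(cmap, periods=rest)
    return model


def flag_outliers(x, y, threshold: float = 3.0) -> np.ndarray:
    """Flag points with |externally studentized residual| > threshold in the
    simple regression of y on x.  A diagnostic only — nothing is removed."""
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    resid = model.get_influence().resid_studentized_external
    return np.abs(resid) > threshold


def plot_correlation_map(cmap: CorrelationMap, model: HarmonicPeakModel | None = None,
                         path=None):
    """Bar chart of epoch r-values with FDR shading and the fitted harmonic."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    colors = np.where(cmap.epochs["significant"], "tab:orange", "tab:gray")
    ax.bar(cmap.midpoints, cmap.r, width=cmap.epochs["end_h"].iloc[0] * 0.9,
           color=colors)
    if model is not None and model.fit is not None:
        grid = np.linspace(0, 24, 481)
        ax.plot(grid, model.fit.predict(grid), color="tab:blue", lw=2)
        for t, h in model.peaks:
            ax.axvline(t, color="tab:blue", ls=":", lw=1)
    ax.set_xlabel("clock time (h)")
    ax.set_ylabel(f"r ({cmap.channel} vs expression)")
    ax.set_xlim(0, 24)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
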