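"""Single- and multi-component cosinor rhythmometry.

The cosinor model expresses a rhythmic signal as

    y(t) = M + sum_k A_k * cos(2*pi*(t - phi_k)/tau_k) + e(t)

with MESOR ``M`` (rhythm-adjusted mean), amplitude ``A_k`` (half the
predictable peak-to-trough extent of component ``k``) and acrophase
``phi_k`` (the local clock time at which component ``k`` peaks, here
reported as a positive clock time in ``[0, tau_k)`` rather than the
classical negative-degrees convention).  The model is linear in
``beta_k = A_k cos(2*pi*phi_k/tau_k)`` and ``gamma_k = A_k sin(...)`` and is
fitted by ordinary least squares.

The zero-amplitude test compares the fitted rhythm against a flat line:

    F = [(TSS - RSS)/(2m)] / [RSS/(n - 2m - 1)]

for ``m`` components, referred to the F(2m, n-2m-1) distribution.
Confidence intervals for M, A_k and phi_k come from the delta method on
the (beta, gamma) covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = ["CosinorComponent", "CosinorFit", "CosinorRegressor", "fit_cosinor",
           "actigraphy_endpoints"]


@dataclass
class CosinorComponent:
    """Fitted parameters of one harmonic component."""

    period: float           # tau, hours
    amplitude: float        # channel units, >= 0
    acrophase: float        # clock time of this component's max, in [0, tau)
    amplitude_ci: tuple[float, float]
    acrophase_ci: tuple[float, float]  # acrophase +/- half-width, hours

    @property
    def amplitude_significant(self) -> bool:
        """Whether the 95% amplitude CI excludes zero."""
        return self.amplitude_ci[0] > 0.0


@dataclass
class CosinorFit:
    """Result of a least-squares cosinor fit."""

    mesor: float
    mesor_ci: tuple[float, float]
    components: list[CosinorComponent]
    rss: float
    tss: float
    n: int
    f_statistic: float
    p_value: float
    peak_times: list[float] = field(default_factory=list)  # clock h, over [0,24)
    degenerate: bool = False

    @property
    def amplitude(self) -> float:
        """Amplitude of the first component (the 24 h one by convention)."""
        return self.components[0].amplitude

    @property
    def acrophase(self) -> float:
        return self.components[0].acrophase

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        y = np.full(t.shape, self.mesor)
        for c in self.components:
            y = y + c.amplitude * np.cos(2 * np.pi * (t - c.acrophase) / c.period)
        return y


def _design(t: np.ndarray, periods: tuple[float, ...]) -> np.ndarray:
    cols = [np.ones_like(t)]
    for tau in periods:
        w = 2 * np.pi * t / tau
        cols.append(np.cos(w))
        cols.append(np.sin(w))
    return np.column_stack(cols)


def acrophase_to_degrees(phi: float, period: float = 24.0) -> float:
    """Convert a clock-time acrophase to the classical negative-degrees form."""
    return -360.0 * (phi % period) / period


class CosinorRegressor(BaseEstimator):
    """Least-squares cosinor estimator with a scikit-learn interface.

    Parameters
    ----------
    periods : sequence of float, default (24.0,)
        Harmonic periods in hours, e.g. ``(24, 12)`` for the two-component
        model used for bimodal daily profiles.
    alpha : float, default 0.05
        Level for the confidence intervals (1 - alpha coverage).

    Attributes
    ----------
    fit_ : CosinorFit
        Full fitted-parameter record.
    mesor_, amplitudes_, acrophases_ : fitted rhythm parameters.
    f_statistic_, p_value_ : zero-amplitude test.
    peak_times_ : clock times (h) of local maxima of the fitted curve
        over one 24 h cycle, found on a 1-minute grid.
    """

    def __init__(self, periods=(24.0,), alpha: float = 0.05):
        self.periods = periods
        self.alpha = alpha

    def fit(self, t, y):
        t = np.asarray(t, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if t.shape != y.shape:
            raise ValueError("t and y must have the same length")
        periods = tuple(float(p) for p in self.periods)
        if len(set(periods)) != len(periods) or any(p <= 0 for p in periods):
            raise ValueError("periods must be distinct and positive")
        m = len(periods)
        n = t.size
        if n < 2 * m + 2:
            raise ValueError(f"need at least {2 * m + 2} points for {m} component(s)")

        X = _design(t, periods)
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            raise np.linalg.LinAlgError(
                "rank-deficient cosinor design (degenerate sampling times)")
        resid = y - X @ coef
        rss = float(resid @ resid)
        tss = float(np.sum((y - y.mean()) ** 2))
        df_resid = n - 2 * m - 1

        degenerate = rss <= max(tss, 1.0) * 1e-14
        if degenerate:
            f_stat, p_val = np.inf, 0.0
            sigma2 = 0.0
        else:
            f_stat = ((tss - rss) / (2 * m)) / (rss / df_resid)
            f_stat = max(f_stat, 0.0)
            p_val = float(stats.f.sf(f_stat, 2 * m, df_resid))
            sigma2 = rss / df_resid

        XtX_inv = np.linalg.inv(X.T @ X)
        cov = sigma2 * XtX_inv
        tcrit = stats.t.ppf(1 - self.alpha / 2, df_resid) if df_resid > 0 else np.nan

        mesor = float(coef[0])
        se_m = float(np.sqrt(cov[0, 0]))
        components = []
        for k, tau in enumerate(periods):
            b, g = coef[1 + 2 * k], coef[2 + 2 * k]
            amp = float(np.hypot(b, g))
            # y = b cos(wt) + g sin(wt) = A cos(w t - theta), theta = atan2(g, b);
            # the maximum is at t = theta/w, mapped into [0, tau)
            phi = float((np.arctan2(g, b) * tau / (2 * np.pi)) % tau)
            sub = cov[1 + 2 * k: 3 + 2 * k, 1 + 2 * k: 3 + 2 * k]
            if amp > 0:
                # delta method: grad A = (b, g)/A; grad theta = (-g, b)/A^2
                ga = np.array([b, g]) / amp
                se_a = float(np.sqrt(ga @ sub @ ga))
                gp = np.array([-g, b]) / amp**2 * tau / (2 * np.pi)
                se_p = float(np.sqrt(gp @ sub @ gp))
            else:
                se_a = float(np.sqrt(sub.trace() / 2))
                se_p = np.nan
            components.append(CosinorComponent(
                period=tau, amplitude=amp, acrophase=phi,
                amplitude_ci=(amp - tcrit * se_a, amp + tcrit * se_a),
                acrophase_ci=(phi - tcrit * se_p, phi + tcrit * se_p),
            ))

        fit = CosinorFit(
            mesor=mesor, mesor_ci=(mesor - tcrit * se_m, mesor + tcrit * se_m),
            components=components, rss=rss, tss=tss, n=n,
            f_statistic=float(f_stat), p_value=float(p_val), degenerate=degenerate,
        )
        fit.peak_times = _peak_times(fit)

        self.fit_ = fit
        self.mesor_ = mesor
        self.amplitudes_ = np.array([c.amplitude for c in components])
        self.acrophases_ = np.array([c.acrophase for c in components])
        self.f_statistic_ = fit.f_statistic
        self.p_value_ = fit.p_value
        self.peak_times_ = fit.peak_times
        return self

    def predict(self, t):
        if not hasattr(self, "fit_"):
            raise AttributeError("CosinorRegressor is not fitted yet")
        return self.fit_.predict(np.asarray(t, dtype=float))


def _peak_times(fit: CosinorFit, grid_minutes: int = 1440) -> list[float]:
    """Local maxima of the fitted curve on a dense cyclic clock grid.

    Evaluated every minute over [0, 24); ties broken by earliest clock
    time through the scan order.
    """
    t = np.arange(grid_minutes) / grid_minutes * 24.0
    y = fit.predict(t)
    if np.ptp(y) <= 1e-15 * max(1.0, abs(fit.mesor)):
        return []
    left = np.roll(y, 1)
    right = np.roll(y, -1)
    is_peak = (y > left) & (y >= right)
    return [float(ti) for ti in t[is_peak]]


def fit_cosinor(t, y, periods=(24.0,), alpha: float = 0.05) -> CosinorFit:
    """Fit a multi-component cosinor by OLS; thin functional wrapper.

    Parameters
    ----------
    t : array of times in hours
    y : array of observations
    periods : harmonic periods in hours

    Returns
    -------
    CosinorFit
    """
    return CosinorRegressor(periods=periods, alpha=alpha).fit(t, y).fit_


def actigraphy_endpoints(series, channel: str, periods=(24.0,),
                         log_light: bool = False,
                         min_coverage: float = 0.8) -> CosinorFit | None:
    """Parametric rhythm endpoints (MESOR, amplitude, acrophase) of a channel.

    Fits the cosinor to all valid minutes, with time measured as clock
    hours since recording start so acrophases land on the local clock.
    Light channels may be log10(x+1)-transformed first (`log_light`);
    the default fits raw values.  Returns None when valid-minute coverage
    is below `min_coverage`.
    """
    y = series.channel(channel)
    if series.coverage() < min_coverage:
        import logging
        logging.getLogger(__name__).warning(
            "%s/%s %s: coverage %.2f below %.2f, endpoints skipped",
            series.participant_id, series.season, channel,
            series.coverage(), min_coverage)
        return None
    start_h = series.start.hour + series.start.minute / 60.0
    t = start_h + series.hours_since_start()
    valid = series.mask & np.isfinite(y)
    yv = y[valid]
    if log_light and channel in ("light", "blue"):
        yv = np.log10(yv + 1.0)
    return fit_cosinor(t[valid], yv, periods=periods)
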