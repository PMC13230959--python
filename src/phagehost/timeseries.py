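"""ddPCR well QC, Poisson absolute quantification, geometric replicate
summaries with LOQ handling, and time-series statistics.

Quantification inverts the Poisson partitioning of template molecules into
droplets: with a fraction ``f = positive/total`` of positive droplets, the
mean copies per droplet is ``lambda = -ln(1 - f)``, giving a concentration
``lambda / droplet_volume`` and ``copies_per_reaction = concentration *
reaction_volume``.  The limit of quantification defaults to 1 copy per 20 uL
reaction.

Replicate summaries are geometric: mean and 95% t-interval on the log10
scale, back-transformed.  Series statistics (ACF/PACF to lag 10, CCF in both
directions, floating-mean Lomb-Scargle on ordinal days, GCV smoothing-spline
trend, coefficient of variation) operate on per-date means of log10
quantifications.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import make_smoothing_spline
from scipy.signal import lombscargle as _lombscargle
from statsmodels.tsa.stattools import acf as _sm_acf, pacf as _sm_pacf

from .core import ValidationError

DEFAULT_DROPLET_VOLUME_NL = 0.85
DEFAULT_REACTION_VOLUME_UL = 20.0
#: template volume assayed per reaction (5 uL DNA), for copies/mL conversion
DEFAULT_SAMPLE_VOLUME_ML = 0.005
DEFAULT_LOQ_COPIES_PER_REACTION = 1.0


@dataclass
class Well:
    """One ddPCR well: droplet counts plus reaction geometry."""

    sample_id: str
    total_droplets: int
    positive_droplets: int
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    reaction_volume_ul: float = DEFAULT_REACTION_VOLUME_UL

    def __post_init__(self) -> None:
        if self.total_droplets < 0 or self.positive_droplets < 0:
            raise ValidationError("droplet counts must be non-negative")
        if self.positive_droplets > self.total_droplets:
            raise ValidationError("positive droplets exceed total droplets")
        if self.droplet_volume_nl <= 0 or self.reaction_volume_ul <= 0:
            raise ValidationError("volumes must be positive")


@dataclass
class QuantResult:
    sample_id: str
    copies_per_reaction: float
    copies_per_ml: float
    below_loq: bool
    saturated: bool


@dataclass
class GeometricSummary:
    geometric_mean: float
    ci_low: float | None
    ci_high: float | None
    n_used: int
    n_excluded: int
    below_loq: bool


@dataclass
class Periodogram:
    frequency: np.ndarray     # cycles per day
    power: np.ndarray         # normalized in [0, 1]
    peak_frequency: float
    peak_power: float

    @property
    def peak_period(self) -> float:
        return 1.0 / self.peak_frequency


@dataclass
class SplineTrend:
    fitted: np.ndarray
    lam: float


def qc_wells(wells: Sequence[Well], min_droplets: int = 10_000) -> list[Well]:
    """Accept wells with at least ``min_droplets`` droplets (inclusive)."""
    return [w for w in wells if w.total_droplets >= min_droplets]


def absolute_quantification(well: Well,
                            loq_copies_per_reaction: float = DEFAULT_LOQ_COPIES_PER_REACTION,
                            sample_volume_ml: float = DEFAULT_SAMPLE_VOLUME_ML
                            ) -> QuantResult:
    """Poisson inversion of a droplet count into absolute copy numbers.

    Saturated wells (every droplet positive) are flagged and quantified with
    a half-droplet correction; callers should treat them as lower bounds.
    """
    if well.total_droplets == 0:
        raise ValidationError("cannot quantify a well with zero droplets")
    saturated = well.positive_droplets == well.total_droplets and well.positive_droplets > 0
    positives = well.positive_droplets - 0.5 if saturated else well.positive_droplets
    frac = positives / well.total_droplets
    lam = -math.log(1.0 - frac)  # copies per droplet
    copies_per_ul = lam / well.droplet_volume_nl * 1000.0
    copies_per_reaction = copies_per_ul * well.reaction_volume_ul
    copies_per_ml = copies_per_reaction / sample_volume_ml
    return QuantResult(sample_id=well.sample_id,
                       copies_per_reaction=copies_per_reaction,
                       copies_per_ml=copies_per_ml,
                       below_loq=copies_per_reaction < loq_copies_per_reaction,
                       saturated=saturated)


def geometric_summary(replicates: Sequence[float], loq: float,
                      confidence: float = 0.95,
                      substitute_at_loq: bool = False) -> GeometricSummary:
    """Geometric mean and back-transformed t-interval of replicate values.

    Non-positive values cannot enter a log mean: by default they are excluded
    (their count is reported); with ``substitute_at_loq`` they are replaced
    by ``loq`` instead.  The ``below_loq`` flag marks summaries whose
    geometric mean falls under ``loq`` (error bars suppressed downstream).
    """
    values = np.asarray(replicates, dtype=float)
    usable = values[values > 0]
    n_excluded = values.size - usable.size
    if substitute_at_loq and n_excluded:
        usable = np.concatenate([usable, np.full(n_excluded, loq)])
        n_excluded = 0
    if usable.size == 0:
        return GeometricSummary(float("nan"), None, None, 0, n_excluded, True)
    logs = np.log10(usable)
    mean = float(logs.mean())
    gm = 10.0 ** mean
    if usable.size < 2:
        return GeometricSummary(gm, None, None, int(usable.size), n_excluded,
                                gm < loq)
    sem = logs.std(ddof=1) / math.sqrt(usable.size)
    t = stats.t.ppf(0.5 + confidence / 2.0, usable.size - 1)
    return GeometricSummary(geometric_mean=gm,
                            ci_low=10.0 ** (mean - t * sem),
                            ci_high=10.0 ** (mean + t * sem),
                            n_used=int(usable.size), n_excluded=n_excluded,
                            below_loq=gm < loq)


def acf_pacf(series: Sequence[float], max_lag: int = 10
             ) -> tuple[np.ndarray, np.ndarray]:
    """Unadjusted (n-denominator) autocorrelations and Durbin-Levinson
    partial autocorrelations out to ``max_lag`` (index 0 is lag 0 = 1)."""
    x = np.asarray(series, dtype=float)
    if x.size <= max_lag:
        raise ValidationError("series must be longer than max_lag")
    if np.ptp(x) == 0:
        raise ValidationError("autocorrelation undefined for a constant series")
    acf_vals = _sm_acf(x, nlags=max_lag, adjusted=False, fft=False)
    pacf_vals = _sm_pacf(x, nlags=max_lag, method="ldb")
    return acf_vals, pacf_vals


def ccf(series_a: Sequence[float], series_b: Sequence[float],
        max_lag: int = 10) -> tuple[np.ndarray, np.ndarray, int]:
    """Cross-correlations of two aligned series for lags -max_lag..+max_lag.

    ``r[k] = corr(a_t, b_{t+k})`` with the biased n-denominator, so a
    positive argmax lag means ``b`` follows ``a``.  Returns (lags, r,
    argmax lag).
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.size != b.size:
        raise ValidationError("series must be aligned to the same dates")
    n = a.size
    if n <= max_lag:
        raise ValidationError("series must be longer than max_lag")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("cross-correlation undefined for constant series")
    da, db = a - a.mean(), b - b.mean()
    denom = n * a.std() * b.std()
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.empty(lags.size)
    for i, k in enumerate(lags):
        if k >= 0:
            r[i] = float(np.dot(da[:n - k], db[k:])) / denom
        else:
            r[i] = float(np.dot(da[-k:], db[:n + k])) / denom
    return lags, r, int(lags[int(np.argmax(r))])


def lomb_scargle(dates: Sequence[float], values: Sequence[float],
                 oversampling: int = 5) -> Periodogram:
    """Floating-mean Lomb-Scargle periodogram on ordinal day numbers.

    Frequencies run from 1/T to n/(2T) (T = observation span) with grid step
    1/(oversampling * T); power uses the standard normalization in [0, 1].
    """
    t = np.asarray(dates, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size or t.size < 4:
        raise ValidationError("need at least 4 aligned observations")
    if np.ptp(y) == 0:
        raise ValidationError("periodogram undefined for a constant series")
    span = float(t.max() - t.min())
    if span <= 0:
        raise ValidationError("dates must span a positive interval")
    n = t.size
    df = 1.0 / (oversampling * span)
    freqs = np.arange(1.0 / span, n / (2.0 * span) + df / 2.0, df)
    power = _lombscargle(t, y, 2.0 * np.pi * freqs, normalize=True,
                         floating_mean=True)
    peak = int(np.argmax(power))
    return Periodogram(frequency=freqs, power=np.asarray(power),
                       peak_frequency=float(freqs[peak]),
                       peak_power=float(power[peak]))


def false_alarm_level(fap: float, n_obs: int, n_freq: int,
                      oversampling: int = 5) -> float:
    """Normalized-power level exceeded with probability ``fap`` under white
    noise, via the single-frequency beta law and an effective number of
    independent frequencies (n_freq / oversampling)."""
    m_eff = max(1, int(round(n_freq / oversampling)))
    p_single = 1.0 - (1.0 - fap) ** (1.0 / m_eff)
    return 1.0 - p_single ** (2.0 / (n_obs - 3.0))


def _gcv_score(x: np.ndarray, y: np.ndarray, lam: float) -> float:
    n = x.size
    fitted = make_smoothing_spline(x, y, lam=lam)(x)
    rss = float(np.sum((y - fitted) ** 2))
    # trace of the linear smoother via its action on unit vectors
    trace = 0.0
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        trace += float(make_smoothing_spline(x, e, lam=lam)(x)[i])
    denom = (n - trace) ** 2
    return n * rss / denom if denom > 0 else float("inf")


def spline_trend(dates: Sequence[float], values: Sequence[float],
                 lam_grid: Sequence[float] | None = None) -> SplineTrend:
    """Cubic smoothing spline with the smoothing parameter chosen by
    generalized cross-validation; returns fitted values on the input dates
    and the chosen parameter."""
    x = np.asarray(dates, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValidationError("need at least 5 observations for a spline trend")
    if np.unique(x).size != x.size:
        raise ValidationError("duplicate dates in spline input")
    order = np.argsort(x)
    x, y = x[order], y[order]
    if lam_grid is None:
        scale = float(np.ptp(x)) ** 3 / max(x.size, 1)
        lam_grid = scale * np.logspace(-8, 4, 25)
    scores = [(_gcv_score(x, y, lam), lam) for lam in lam_grid]
    best_lam = min(scores)[1]
    fitted = make_smoothing_spline(x, y, lam=best_lam)(x)
    inverse = np.empty_like(fitted)
    inverse[order] = fitted
    return SplineTrend(fitted=inverse, lam=float(best_lam))


def coefficient_of_variation(log_series: Sequence[float]) -> float:
    """Sample standard deviation over sample mean of log10 quantifications."""
    x = np.asarray(log_series, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise ValidationError("coefficient of variation undefined for zero mean")
    return float(x.std(ddof=1) / mean)
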