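"""Growth-curve variables and CFU survival arithmetic.

Three variables summarize an OD600 time series: the maximum specific
growth rate (slope of the exponential phase on natural-log OD), the lag
time (where the max-slope tangent in log space crosses the initial density
— the classic graphical lag), and the growth efficiency (total density
gain to stationary phase, on the linear scale).  The rate comes from a
sliding-window least-squares fit so a single noisy reading cannot set it.

Survival after an acid challenge is the percentage of colony-forming units
remaining relative to time zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "GrowthCurve",
    "GrowthVariables",
    "GrowthComparison",
    "SurvivalSeries",
    "growth_variables",
    "compare_growth",
    "survival_rate",
    "death_rate",
]

logger = logging.getLogger(__name__)

OD_FLOOR = 1e-4  # readings at/below the blank floor are clipped here


@dataclass
class GrowthCurve:
    """An OD600 time series for one strain/condition."""

    times: np.ndarray
    od: np.ndarray
    label: str = ""
    clipped: bool = field(default=False, init=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape or self.times.ndim != 1:
            raise ValueError("times and od must be 1-D arrays of equal length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od <= OD_FLOOR):
            self.clipped = True
            logger.warning(
                "%s: %d OD readings at/below %g clipped",
                self.label, int(np.sum(self.od <= OD_FLOOR)), OD_FLOOR,
            )
            self.od = np.maximum(self.od, OD_FLOOR)

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class GrowthVariables:
    """(lag, rate, efficiency) summary of one curve.

    ``lag`` is in hours (NaN when the curve never grows), ``rate`` in /h on
    the natural-log scale, ``efficiency`` is ΔOD600.  ``window`` is the
    index range [start, stop) of points used for the max-slope tangent.
    ``lag_clipped`` flags a negative tangent intercept clipped to 0.
    """

    lag: float
    rate: float
    efficiency: float
    window: tuple[int, int]
    lag_clipped: bool = False

    @property
    def lag_defined(self) -> bool:
        return not math.isnan(self.lag)


def growth_variables(
    curve: GrowthCurve,
    window_size: int = 4,
    n_initial: int | None = None,
    log_scale: bool = True,
    median_filter: bool = False,
) -> GrowthVariables:
    """Extract (lag, rate, efficiency) from one growth curve.

    Least-squares lines are fit over every contiguous window of
    ``window_size`` points on ln(OD); the rate is the maximum slope (the
    earliest window on ties).  The lag is where that tangent crosses
    ln(od_initial), with od_initial the mean of the first
    ``max(2, window_size // 2)`` readings (override with ``n_initial``).
    Efficiency is max(OD) − od_initial on the linear scale.

    A flat or declining curve gets rate 0, lag NaN.  ``log_scale=False``
    fits the windows on linear OD instead; ``median_filter`` applies a
    3-point running median first (for noisy plates).
    """
    n = len(curve)
    if n < 5:
        raise ValueError(f"need >= 5 points for variable extraction, got {n}")
    if window_size < 3 or window_size > n:
        raise ValueError(f"window_size must be in [3, {n}], got {window_size}")

    od = curve.od
    if median_filter:
        padded = np.concatenate([od[:1], od, od[-1:]])
        od = np.median(sliding_window_view(padded, 3), axis=1)
    y = np.log(od) if log_scale else od
    t = curve.times

    tw = sliding_window_view(t, window_size)
    yw = sliding_window_view(y, window_size)
    tm = tw.mean(axis=1, keepdims=True)
    ym = yw.mean(axis=1, keepdims=True)
    cov = ((tw - tm) * (yw - ym)).sum(axis=1)
    var = ((tw - tm) ** 2).sum(axis=1)
    slopes = cov / var
    intercepts = ym[:, 0] - slopes * tm[:, 0]

    best = int(np.argmax(slopes))  # argmax -> earliest window on exact ties
    rate = float(slopes[best])
    k = n_initial if n_initial is not None else max(2, window_size // 2)
    od_initial = float(od[:k].mean())
    efficiency = max(float(od.max()) - od_initial, 0.0)

    if rate <= 0:
        return GrowthVariables(
            lag=math.nan, rate=0.0, efficiency=efficiency,
            window=(best, best + window_size),
        )
    y_initial = math.log(od_initial) if log_scale else od_initial
    lag = (y_initial - float(intercepts[best])) / rate
    clipped = lag < 0
    return GrowthVariables(
        lag=max(lag, 0.0), rate=rate, efficiency=efficiency,
        window=(best, best + window_size), lag_clipped=clipped,
    )


@dataclass
class GrowthComparison:
    """a vs b: ratios for rate and efficiency, difference for lag (hours)."""

    rate_ratio: float
    efficiency_ratio: float
    lag_difference: float


def compare_growth(a: GrowthVariables, b: GrowthVariables) -> GrowthComparison:
    lag_diff = (
        a.lag - b.lag if (a.lag_defined and b.lag_defined) else math.nan
    )
    return GrowthComparison(
        rate_ratio=a.rate / b.rate if b.rate > 0 else math.inf,
        efficiency_ratio=a.efficiency / b.efficiency
        if b.efficiency > 0
        else math.inf,
        lag_difference=lag_diff,
    )


@dataclass
class SurvivalSeries:
    """Dilution-corrected CFU/mL over time after a stress challenge."""

    times: np.ndarray
    cfu: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cfu = np.asarray(self.cfu, dtype=float)
        if self.times.shape != self.cfu.shape or self.times.ndim != 1:
            raise ValueError("times and cfu must be 1-D arrays of equal length")
        if np.any(self.cfu < 0):
            raise ValueError("cfu must be >= 0")


def survival_rate(series: SurvivalSeries) -> list[tuple[float, float]]:
    """Per time point: 100 × CFU(t) / CFU(0).  survival(0) is exactly 100."""
    if series.cfu[0] <= 0:
        raise ValueError("CFU at time zero must be > 0")
    return [
        (float(t), 100.0 * float(c) / float(series.cfu[0]))
        for t, c in zip(series.times, series.cfu)
    ]


def death_rate(series: SurvivalSeries) -> float:
    """First-order death constant k (/h) from a log-linear CFU fit.

    Zero-CFU points are excluded (log undefined); requires >= 2 positive
    points.  Returns a positive k for declining viability.
    """
    mask = series.cfu > 0
    if mask.sum() < 2:
        raise ValueError("need >= 2 positive CFU counts to fit a death rate")
    slope = np.polyfit(series.times[mask], np.log(series.cfu[mask]), 1)[0]
    return float(-slope)
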