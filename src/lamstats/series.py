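"""Age-indexed proxy and state series, and the window/interpolation primitives.

Every record in a sediment-core analysis is a sequence of (age, value)
samples, unevenly spaced in time because cores are sampled at fixed depth
increments while sedimentation rate varies.  Ages are in ka (thousand years
before present) and increase into the past.  Missing measurements are carried
as NaN and excluded sample-by-sample from each statistic; they are never
imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ProxySeries",
    "StateSeries",
    "LaminatedInterval",
    "IntervalTable",
    "running_mean",
    "interpolate_uniform",
    "moving_window_stats",
    "align_and_subtract",
    "elemental_ratio",
    "states_from_intervals",
    "group_means",
]


def _float_array(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D sequence")
    return arr


@dataclass(frozen=True)
class ProxySeries:
    """One proxy record: strictly age-ordered samples with optional gaps.

    Parameters
    ----------
    name : str
        Proxy identifier, e.g. ``"d18O"`` or ``"si_ti"``.
    ages : array-like of float
        Sample ages in ka, strictly increasing, all finite and >= 0.
    values : array-like of float
        Proxy values; NaN marks a missing measurement.
    units : str
        Measurement units (e.g. ``"permil"``); informational.
    depths : array-like of float, optional
        Core depths in metres, same length as ``ages``.
    """

    name: str
    ages: np.ndarray
    values: np.ndarray
    units: str = ""
    depths: np.ndarray | None = None

    def __post_init__(self):
        ages = _float_array(self.ages)
        values = _float_array(self.values)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "values", values)
        if self.depths is not None:
            depths = _float_array(self.depths)
            if len(depths) != len(ages):
                raise ValueError("depths length must match ages")
            object.__setattr__(self, "depths", depths)
        if len(ages) == 0:
            raise ValueError(f"proxy series {self.name!r} is empty")
        if len(values) != len(ages):
            raise ValueError("ages and values must have equal length")
        if not np.all(np.isfinite(ages)):
            raise ValueError("ages must be finite")
        if np.any(ages < 0):
            raise ValueError("ages must be non-negative (ka before present)")
        if len(ages) > 1 and not np.all(np.diff(ages) > 0):
            raise ValueError(f"ages of {self.name!r} must be strictly increasing")

    def __len__(self) -> int:
        return len(self.ages)

    @property
    def usable(self) -> np.ndarray:
        """Boolean mask of non-missing samples."""
        return np.isfinite(self.values)

    @property
    def n_usable(self) -> int:
        return int(self.usable.sum())

    def with_values(self, values, name: str | None = None,
                    units: str | None = None) -> "ProxySeries":
        """Same ages, new values (used by every transform)."""
        return replace(
            self,
            values=_float_array(values),
            name=self.name if name is None else name,
            units=self.units if units is None else units,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"age_ka": self.ages, self.name: self.values})
        if self.depths is not None:
            df.insert(1, "depth_m", self.depths)
        return df


@dataclass(frozen=True)
class StateSeries:
    """Per-sample binary lamination state on a strictly increasing age axis.

    ``laminated`` is True where the sediment at that sample is laminated
    (deposited under hypoxia, [O2] too low for burrowing fauna).
    """

    ages: np.ndarray
    laminated: np.ndarray

    def __post_init__(self):
        ages = _float_array(self.ages)
        lam = np.asarray(self.laminated, dtype=bool)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "laminated", lam)
        if len(lam) != len(ages):
            raise ValueError("ages and states must have equal length")
        if len(ages) > 1 and not np.all(np.diff(ages) > 0):
            raise ValueError("ages must be strictly increasing")

    def __len__(self) -> int:
        return len(self.ages)

    @property
    def n_laminated(self) -> int:
        return int(self.laminated.sum())


@dataclass(frozen=True)
class LaminatedInterval:
    """A labelled laminated span [start_age_ka, end_age_ka], closed on both ends."""

    label: str
    start_age_ka: float
    end_age_ka: float

    def __post_init__(self):
        if not self.start_age_ka < self.end_age_ka:
            raise ValueError(
                f"interval {self.label!r}: start {self.start_age_ka} must be "
                f"< end {self.end_age_ka}"
            )


@dataclass(frozen=True)
class IntervalTable:
    """Non-overlapping, uniquely labelled laminated intervals."""

    intervals: tuple = field(default_factory=tuple)

    def __post_init__(self):
        iv = tuple(self.intervals)
        object.__setattr__(self, "intervals", iv)
        labels = [i.label for i in iv]
        if len(set(labels)) != len(labels):
            raise ValueError("interval labels must be unique")
        by_start = sorted(iv, key=lambda i: i.start_age_ka)
        for a, b in zip(by_start, by_start[1:]):
            if b.start_age_ka < a.end_age_ka:
                raise ValueError(
                    f"intervals {a.label!r} and {b.label!r} overlap"
                )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def sorted(self) -> "IntervalTable":
        return IntervalTable(tuple(sorted(self.intervals,
                                          key=lambda i: i.start_age_ka)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [i.label for i in self.intervals],
                "start_age_ka": [i.start_age_ka for i in self.intervals],
                "end_age_ka": [i.end_age_ka for i in self.intervals],
            }
        )


# ---------------------------------------------------------------------------
# primitives


def running_mean(series: ProxySeries, k: int = 3) -> ProxySeries:
    """Centered k-point running mean; edge windows truncate to available points.

    Missing values are excluded from each window's mean (a window of only
    missing values stays missing).  ``k`` must be odd so the window centers
    on the sample.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError(f"k must be a positive odd integer, got {k}")
    sm = (
        pd.Series(series.values)
        .rolling(window=k, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return series.with_values(sm, name=f"{series.name}_rm{k}")


def interpolate_uniform(series: ProxySeries, step_ka: float = 1.0) -> ProxySeries:
    """Linear interpolation onto a uniform age grid covering the data span.

    The grid starts at the first usable age and advances by ``step_ka``
    without extrapolating past the last usable age.  Missing samples are
    dropped before interpolating (they carry no information for the grid).
    """
    if step_ka <= 0:
        raise ValueError("step_ka must be positive")
    ok = series.usable
    if ok.sum() < 2:
        raise ValueError(
            f"series {series.name!r} needs >= 2 non-missing samples to interpolate"
        )
    a = series.ages[ok]
    v = series.values[ok]
    n_steps = int(np.floor((a[-1] - a[0]) / step_ka + 1e-9))
    grid = a[0] + step_ka * np.arange(n_steps + 1)
    return ProxySeries(
        name=series.name,
        ages=grid,
        values=np.interp(grid, a, v),
        units=series.units,
    )


def moving_window_stats(
    series: ProxySeries, window_ka: float = 100.0
) -> tuple[ProxySeries, ProxySeries]:
    """Mean and sample SD over a centered age window at each sample.

    The window at age t is the closed interval [t - window_ka/2,
    t + window_ka/2]; membership is by age, not by sample count, so uneven
    sampling widens or narrows the member set naturally.  SD uses the n-1
    denominator; windows with fewer than 2 usable samples yield missing SD.
    """
    if window_ka <= 0:
        raise ValueError("window_ka must be positive")
    ages = series.ages
    vals = series.values
    half = window_ka / 2.0
    lo = np.searchsorted(ages, ages - half, side="left")
    hi = np.searchsorted(ages, ages + half, side="right")
    n = len(ages)
    means = np.full(n, np.nan)
    sds = np.full(n, np.nan)
    for i in range(n):
        w = vals[lo[i]:hi[i]]
        w = w[np.isfinite(w)]
        if w.size >= 1:
            means[i] = w.mean()
        if w.size >= 2:
            sds[i] = w.std(ddof=1)
    return (
        series.with_values(means, name=f"{series.name}_mean"),
        series.with_values(sds, name=f"{series.name}_sd"),
    )


def align_and_subtract(a: ProxySeries, b: ProxySeries) -> ProxySeries:
    """a minus b, with b linearly interpolated onto a's age axis.

    Ages of ``a`` outside b's (usable) span become missing — differencing
    against an extrapolated reference would fabricate signal.  Fully
    disjoint spans give an all-missing result with a warning.
    """
    okb = b.usable
    if okb.sum() < 2:
        raise ValueError(f"reference series {b.name!r} needs >= 2 usable samples")
    ba = b.ages[okb]
    bv = b.values[okb]
    inside = (a.ages >= ba[0]) & (a.ages <= ba[-1])
    out = np.full(len(a), np.nan)
    out[inside] = a.values[inside] - np.interp(a.ages[inside], ba, bv)
    if not inside.any():
        warnings.warn(
            f"age spans of {a.name!r} and {b.name!r} are disjoint; "
            "difference is all-missing",
            stacklevel=2,
        )
    return a.with_values(out, name=f"{a.name}_minus_{b.name}")


def elemental_ratio(numerator: ProxySeries, denominator: ProxySeries) -> ProxySeries:
    """Pointwise element-mass ratio (e.g. Si/Ti); bad denominators go missing.

    Both series must share the same age axis.  A denominator that is
    missing or <= 0 yields a missing ratio rather than an exception or an
    infinity.
    """
    if len(numerator) != len(denominator) or not np.array_equal(
        numerator.ages, denominator.ages
    ):
        raise ValueError(
            f"{numerator.name!r} and {denominator.name!r} must share the same ages"
        )
    den = denominator.values
    bad = ~np.isfinite(den) | (den <= 0)
    out = np.full(len(numerator), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        out[~bad] = numerator.values[~bad] / den[~bad]
    return numerator.with_values(
        out, name=f"{numerator.name}_{denominator.name}_ratio", units=""
    )


def states_from_intervals(ages, intervals: IntervalTable) -> StateSeries:
    """Mark each age laminated iff it falls inside any interval (closed ends)."""
    ages = _float_array(ages)
    lam = np.zeros(len(ages), dtype=bool)
    for iv in intervals:
        lam |= (ages >= iv.start_age_ka) & (ages <= iv.end_age_ka)
    return StateSeries(ages=ages, laminated=lam)


def group_means(
    values: ProxySeries, states: StateSeries
) -> tuple[float, float, float]:
    """Mean of a proxy in laminated vs nonlaminated samples, and their difference.

    Missing values are excluded.  If either group has no usable sample its
    mean — and the difference — is NaN (undefined), never an exception.
    Returns ``(mean_laminated, mean_nonlaminated, difference)``.
    """
    if len(values) != len(states) or not np.array_equal(values.ages, states.ages):
        raise ValueError("values and states must share the same ages")
    ok = values.usable
    lam = states.laminated & ok
    non = ~states.laminated & ok
    mean_lam = float(values.values[lam].mean()) if lam.any() else float("nan")
    mean_non = float(values.values[non].mean()) if non.any() else float("nan")
    return mean_lam, mean_non, mean_lam - mean_non
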