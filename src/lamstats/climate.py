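"""Glacial / Interglacial / Intermediate classification from benthic δ18O.

Benthic foraminiferal δ18O tracks global ice volume: higher values mean a
more glacial climate.  A sample is called Glacial when its raw δ18O sits
more than one standard deviation above the local baseline, Interglacial
when more than one standard deviation below, Intermediate otherwise.  The
baseline is a 100-ka moving window over a three-point running mean of the
record interpolated to a uniform 1-ka grid, so that the window statistics
reflect orbital-band variability rather than sampling density.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

from .series import (
    IntervalTable,
    ProxySeries,
    interpolate_uniform,
    moving_window_stats,
    running_mean,
)

__all__ = ["ClimateLabel", "ClimateSeries", "classify_samples",
           "interval_climate", "climate_summary"]


class ClimateLabel(str, enum.Enum):
    GLACIAL = "Glacial"
    INTERGLACIAL = "Interglacial"
    INTERMEDIATE = "Intermediate"

    def __str__(self) -> str:  # plain value in CSV/JSON output
        return self.value


@dataclass(frozen=True)
class ClimateSeries:
    """Per-sample climate labels plus the baseline used to assign them.

    ``baseline_mean`` / ``baseline_sd`` are the window statistics
    interpolated back to the sample ages, so each label can be re-derived
    from the stored numbers.
    """

    ages: np.ndarray
    labels: tuple
    d18O: np.ndarray
    baseline_mean: np.ndarray
    baseline_sd: np.ndarray

    def __len__(self) -> int:
        return len(self.ages)

    def label_values(self) -> np.ndarray:
        return np.array([lab.value for lab in self.labels])


def classify_samples(
    d18O: ProxySeries,
    smooth_k: int = 3,
    step_ka: float = 1.0,
    window_ka: float = 100.0,
    compare_smoothed: bool = False,
) -> ClimateSeries:
    """Label every δ18O sample Glacial / Interglacial / Intermediate.

    Pipeline: ``running_mean(smooth_k)`` on the raw samples →
    ``interpolate_uniform(step_ka)`` → ``moving_window_stats(window_ka)``
    on the smoothed grid.  Each original sample is then compared against
    mean(t) ± sd(t), linearly interpolated from the grid (constant beyond
    the grid ends).  By default the sample's *raw* δ18O is the test value;
    ``compare_smoothed=True`` compares its smoothed value instead.

    A missing or zero baseline sd makes the sample Intermediate: a window
    with no variability carries no glacial/interglacial information.
    Missing δ18O samples are labelled Intermediate as well.
    """
    if d18O.n_usable < 2:
        raise ValueError("need >= 2 usable d18O samples to classify")
    smoothed = running_mean(d18O, k=smooth_k)
    grid = interpolate_uniform(smoothed, step_ka=step_ka)
    gmean, gsd = moving_window_stats(grid, window_ka=window_ka)

    bmean = _interp_const_ends(d18O.ages, gmean.ages, gmean.values)
    bsd = _interp_const_ends(d18O.ages, gsd.ages, gsd.values)

    test_vals = smoothed.values if compare_smoothed else d18O.values
    labels = []
    for x, m, s in zip(test_vals, bmean, bsd):
        if not np.isfinite(x) or not np.isfinite(s) or s <= 0 or not np.isfinite(m):
            labels.append(ClimateLabel.INTERMEDIATE)
        elif x > m + s:
            labels.append(ClimateLabel.GLACIAL)
        elif x < m - s:
            labels.append(ClimateLabel.INTERGLACIAL)
        else:
            labels.append(ClimateLabel.INTERMEDIATE)
    return ClimateSeries(
        ages=d18O.ages.copy(),
        labels=tuple(labels),
        d18O=d18O.values.copy(),
        baseline_mean=bmean,
        baseline_sd=bsd,
    )


def _interp_const_ends(x, xp, fp) -> np.ndarray:
    """Linear interpolation, constant beyond the grid; NaNs in fp propagate
    only where x falls in an all-NaN neighbourhood."""
    ok = np.isfinite(fp)
    if not ok.any():
        return np.full(len(x), np.nan)
    return np.interp(x, xp[ok], fp[ok])


def interval_climate(
    intervals: IntervalTable, climate: ClimateSeries
) -> dict[str, frozenset]:
    """The set of climate labels seen among samples inside each interval.

    Interval endpoints are closed.  An interval containing no samples maps
    to an empty set, with a warning (it cannot be climate-typed).
    """
    out: dict[str, frozenset] = {}
    for iv in intervals:
        inside = (climate.ages >= iv.start_age_ka) & (climate.ages <= iv.end_age_ka)
        labs = frozenset(climate.labels[i] for i in np.flatnonzero(inside))
        if not labs:
            warnings.warn(
                f"laminated interval {iv.label!r} contains no samples",
                stacklevel=2,
            )
        out[iv.label] = labs
    return out


def climate_summary(
    intervals: IntervalTable, climate: ClimateSeries
) -> dict[str, int]:
    """Counts of intervals by glacial involvement.

    Returns counts of intervals whose label set (``without_glacial``)
    excludes Glacial, (``with_glacial``) includes Glacial, and
    (``exclusively_glacial``) is exactly {Glacial}.  Empty label sets
    (intervals with no samples) fall in ``without_glacial``.
    """
    sets = interval_climate(intervals, climate)
    without = sum(1 for s in sets.values() if ClimateLabel.GLACIAL not in s)
    with_g = sum(1 for s in sets.values() if ClimateLabel.GLACIAL in s)
    only_g = sum(1 for s in sets.values() if s == frozenset({ClimateLabel.GLACIAL}))
    return {
        "n_intervals": len(sets),
        "without_glacial": without,
        "with_glacial": with_g,
        "exclusively_glacial": only_g,
    }
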