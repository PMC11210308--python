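"""Moving-window z-scores for δ15N nitrate-utilization peaks.

Bulk-sediment δ15N rises when phytoplankton draw the surface nitrate pool
down more completely.  To flag statistically high excursions against a
drifting local background, the record is first detrended (ordinary least
squares in age) and scaled to unit residual variance, giving χ; then

    z_t = (χ_t − x̄_t) / σ_t

where x̄_t and σ_t are the mean and sample SD of χ over a centered 100-ka
age window at time t.  z ≥ 1.645 marks a one-sided significantly high
value at the 5% level under a normal reference; low excursions are
reported but never flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import ProxySeries, StateSeries, group_means, moving_window_stats

__all__ = ["ZScoreSeries", "detrend_normalize", "compute_zscores",
           "zscore_group_comparison", "ONE_SIDED_95_THRESHOLD"]

# one-sided normal critical value at P < 0.05, to the precision used in practice
ONE_SIDED_95_THRESHOLD = 1.645


@dataclass(frozen=True)
class ZScoreSeries:
    """Per-sample z-scores with the window statistics that produced them."""

    ages: np.ndarray
    chi: np.ndarray            # detrended-normalized values
    running_mean: np.ndarray   # windowed mean of chi at each sample
    running_sd: np.ndarray     # windowed sample SD of chi at each sample
    z: np.ndarray              # (chi - mean)/sd; NaN where sd unusable
    significant: np.ndarray    # z >= threshold (one-sided, high side only)
    threshold: float
    window_ka: float

    def __len__(self) -> int:
        return len(self.ages)

    def as_proxy(self, name: str = "z") -> ProxySeries:
        return ProxySeries(name=name, ages=self.ages, values=self.z)


def detrend_normalize(series: ProxySeries) -> ProxySeries:
    """Remove the OLS linear trend in age and scale residuals to unit variance.

    Fits value = a + b·age on the non-missing samples, subtracts the fit,
    and divides by the residuals' sample standard deviation (n−1).  Missing
    samples stay missing.  A record with (numerically) zero residual
    variance is rejected — it has no anomalies to score.
    """
    ok = series.usable
    if ok.sum() < 3:
        raise ValueError(
            f"series {series.name!r} needs >= 3 usable samples to detrend"
        )
    a = series.ages[ok]
    v = series.values[ok]
    slope, intercept = np.polyfit(a, v, 1)
    resid_ok = v - (intercept + slope * a)
    sd = resid_ok.std(ddof=1)
    if not np.isfinite(sd) or sd <= np.finfo(float).eps * max(1.0, np.abs(v).max()):
        raise ValueError(
            f"series {series.name!r} has zero residual variance after detrending; "
            "nothing to normalize"
        )
    out = (series.values - (intercept + slope * series.ages)) / sd
    return series.with_values(out, name=f"{series.name}_chi", units="")


def compute_zscores(
    series: ProxySeries,
    window_ka: float = 100.0,
    threshold: float = ONE_SIDED_95_THRESHOLD,
) -> ZScoreSeries:
    """Moving-window z-score of a (detrended-normalized) record.

    Windows are centered, closed and age-based, shrinking at the record
    ends.  Samples whose window holds fewer than 2 usable values, or whose
    window SD is zero, get a missing z and are never significant.
    """
    mean_s, sd_s = moving_window_stats(series, window_ka=window_ka)
    m = mean_s.values
    s = sd_s.values
    z = np.full(len(series), np.nan)
    usable = np.isfinite(series.values) & np.isfinite(m) & np.isfinite(s) & (s > 0)
    z[usable] = (series.values[usable] - m[usable]) / s[usable]
    sig = np.zeros(len(series), dtype=bool)
    sig[usable] = z[usable] >= threshold
    return ZScoreSeries(
        ages=series.ages.copy(),
        chi=series.values.copy(),
        running_mean=m,
        running_sd=s,
        z=z,
        significant=sig,
        threshold=threshold,
        window_ka=window_ka,
    )


def zscore_group_comparison(
    zs: ZScoreSeries, states: StateSeries
) -> tuple[float, float, float]:
    """Mean z in laminated vs nonlaminated samples and their difference."""
    return group_means(zs.as_proxy(), states)
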