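"""Independent brute-force oracles, written with plain loops.

These deliberately avoid the package's primitives (and vectorized numpy
where reasonable) so that agreement with the implementation is evidence,
not tautology.
"""

from __future__ import annotations

import itertools
import math


def oracle_running_mean(values, k):
    """Centered k-point mean, truncated windows at the edges, NaN skipped."""
    n = len(values)
    h = k // 2
    out = []
    for i in range(n):
        window = [values[j] for j in range(max(0, i - h), min(n, i + h + 1))
                  if not math.isnan(values[j])]
        out.append(math.fsum(window) / len(window) if window else math.nan)
    return out


def oracle_interp(x, xp, fp):
    """Piecewise-linear interpolation; clamps to the end values outside."""
    out = []
    for xi in x:
        if xi <= xp[0]:
            out.append(fp[0])
            continue
        if xi >= xp[-1]:
            out.append(fp[-1])
            continue
        j = 0
        while xp[j + 1] < xi:
            j += 1
        t = (xi - xp[j]) / (xp[j + 1] - xp[j])
        out.append(fp[j] + t * (fp[j + 1] - fp[j]))
    return out


def oracle_window_stats(ages, values, window_ka):
    """Closed centered age-window mean and n-1 SD per sample."""
    half = window_ka / 2.0
    means, sds = [], []
    for t in ages:
        w = [v for a, v in zip(ages, values)
             if t - half <= a <= t + half and not math.isnan(v)]
        if not w:
            means.append(math.nan)
        else:
            means.append(math.fsum(w) / len(w))
        if len(w) < 2:
            sds.append(math.nan)
        else:
            m = math.fsum(w) / len(w)
            sds.append(math.sqrt(math.fsum((v - m) ** 2 for v in w) / (len(w) - 1)))
    return means, sds


def oracle_classify(ages, d18O, smooth_k=3, step_ka=1.0, window_ka=100.0):
    """Full climate-label pipeline re-derived with loops.

    Smooth raw samples with a truncated centered running mean, put the
    smoothed curve on a uniform grid, take closed 100-ka window stats on
    the grid, interpolate them back to the sample ages (constant beyond
    the grid), and compare each raw sample against mean +/- sd.
    """
    sm = oracle_running_mean(list(d18O), smooth_k)
    usable = [(a, v) for a, v in zip(ages, sm) if not math.isnan(v)]
    a0, a1 = usable[0][0], usable[-1][0]
    n_steps = int(math.floor((a1 - a0) / step_ka + 1e-9))
    grid = [a0 + step_ka * i for i in range(n_steps + 1)]
    gvals = oracle_interp(grid, [a for a, _ in usable], [v for _, v in usable])
    gmean, gsd = oracle_window_stats(grid, gvals, window_ka)
    bmean = oracle_interp(list(ages), grid, gmean)
    bsd = oracle_interp(list(ages), grid, gsd)
    labels = []
    for x, m, s in zip(d18O, bmean, bsd):
        if math.isnan(x) or math.isnan(s) or s <= 0 or math.isnan(m):
            labels.append("Intermediate")
        elif x > m + s:
            labels.append("Glacial")
        elif x < m - s:
            labels.append("Interglacial")
        else:
            labels.append("Intermediate")
    return labels, bmean, bsd


def oracle_zscores(ages, chi, window_ka=100.0, threshold=1.645):
    """Moving-window z-scores re-derived with loops."""
    means, sds = oracle_window_stats(list(ages), list(chi), window_ka)
    zs, sig = [], []
    for x, m, s in zip(chi, means, sds):
        if math.isnan(x) or math.isnan(m) or math.isnan(s) or s <= 0:
            zs.append(math.nan)
            sig.append(False)
        else:
            z = (x - m) / s
            zs.append(z)
            sig.append(z >= threshold)
    return zs, sig


def enumerate_null(values, first_laminated, p_NL, p_LN, stat_kind,
                   target_indicator=None):
    """Exact null distribution over all 2^(n-1) labellings of a small record.

    Chains start at the observed first state (probability one) and step
    with the given switching probabilities.  Returns a list of
    (probability, statistic) for labellings whose statistic is defined;
    probabilities are NOT renormalized (invalid labellings keep their
    mass excluded, as the Monte Carlo engine discards those iterations —
    callers renormalize).
    """
    n = len(values)
    out = []
    for tail in itertools.product([False, True], repeat=n - 1):
        lam = (first_laminated,) + tail
        prob = 1.0
        for prev, cur in zip(lam, lam[1:]):
            if prev:
                prob *= p_LN if not cur else (1.0 - p_LN)
            else:
                prob *= p_NL if cur else (1.0 - p_NL)
        if prob == 0.0:
            continue
        lam_vals = [v for v, s in zip(values, lam) if s and not math.isnan(v)]
        non_vals = [v for v, s in zip(values, lam) if not s and not math.isnan(v)]
        if stat_kind == "diff":
            if not lam_vals or not non_vals:
                continue
            stat = (math.fsum(lam_vals) / len(lam_vals)
                    - math.fsum(non_vals) / len(non_vals))
        elif stat_kind == "during":
            if not lam_vals:
                continue
            stat = math.fsum(lam_vals) / len(lam_vals)
        elif stat_kind == "proportion":
            idx = [i for i, s in enumerate(lam) if s]
            if not idx:
                continue
            stat = math.fsum(target_indicator[i] for i in idx) / len(idx)
        else:
            raise ValueError(stat_kind)
        out.append((prob, stat))
    return out


def exact_p_two_sided(enumerated, observed):
    """Exact two-sided-about-mean p from an enumerated null."""
    total = math.fsum(p for p, _ in enumerated)
    mean = math.fsum(p * s for p, s in enumerated) / total
    dev = abs(observed - mean)
    mass = math.fsum(p for p, s in enumerated if abs(s - mean) >= dev - 1e-12)
    return mass / total
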