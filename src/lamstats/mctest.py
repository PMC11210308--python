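"""Markov-chain Monte Carlo randomization tests for lamination records.

Proxy records from a sediment core are autocorrelated and unevenly
sampled, so two-sample t tests and chi-square tests of association are
invalid for comparing laminated against nonlaminated samples.  The
randomization approach keeps the proxy values fixed and re-draws the
binary lamination labelling from a two-state Markov chain whose switching
probabilities are estimated from consecutive samples of the observed
record — preserving the run-length (autocorrelation) structure of the
event series under the null of no association.

Three test statistics are supported:

* mean difference — proxy mean in laminated minus nonlaminated samples;
* state proportion — fraction of laminated samples carrying a given
  climate label (e.g. Glacial);
* mean during events — proxy mean over laminated samples only (used for
  relative sea level).

The p-value is the proportion of simulated statistics as extreme as or
more extreme than the observed one; "extreme" defaults to absolute
deviation from the null-distribution mean (two-sided), with a one-sided
mode available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .climate import ClimateLabel, ClimateSeries
from .series import ProxySeries, StateSeries

__all__ = [
    "TransitionProbs",
    "MCTestResult",
    "estimate_transitions",
    "simulate_states",
    "p_value",
    "mc_test_mean_difference",
    "mc_test_state_proportion",
    "mc_test_mean_during_events",
    "TWO_SIDED",
    "ONE_SIDED",
]

TWO_SIDED = "two_sided_about_null_mean"
ONE_SIDED = "one_sided_observed_direction"
_SIDEDNESS = (TWO_SIDED, ONE_SIDED)

_CHUNK = 2048  # simulated chains per vectorized block


@dataclass(frozen=True)
class TransitionProbs:
    """Per-consecutive-sample switching probabilities of the two-state chain.

    ``p_NL`` is P(laminated at i+1 | nonlaminated at i); ``p_LN`` the
    reverse switch.  Age gaps between consecutive samples are ignored —
    the chain steps per sample, exactly as the labels were recorded.
    """

    p_NL: float
    p_LN: float
    n_transitions_from_N: int = 0
    n_transitions_from_L: int = 0

    def __post_init__(self):
        for nm, p in (("p_NL", self.p_NL), ("p_LN", self.p_LN)):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{nm} must be in [0, 1], got {p}")
        if self.n_transitions_from_N < 0 or self.n_transitions_from_L < 0:
            raise ValueError("transition counts must be non-negative")

    @property
    def stationary_laminated_fraction(self) -> float:
        """Long-run laminated fraction p_NL/(p_NL + p_LN); NaN if both 0."""
        s = self.p_NL + self.p_LN
        return self.p_NL / s if s > 0 else float("nan")


@dataclass(frozen=True)
class MCTestResult:
    """Result of one randomization test.

    ``n_valid`` counts iterations whose statistic was defined (e.g. both
    groups nonempty); discarded iterations are logged by the caller.  A
    result with ``n_valid == 0`` is invalid and carries a NaN p-value.
    """

    statistic_name: str
    observed: float
    null_stats: np.ndarray
    n_iter: int
    n_valid: int
    p_value: float
    sidedness: str
    seed: int

    @property
    def valid(self) -> bool:
        return self.n_valid > 0 and np.isfinite(self.observed)

    def p_value_display(self) -> str:
        """Human-readable p; a plain-proportion 0 is reported as a bound."""
        if not self.valid:
            return "undefined"
        if self.p_value == 0.0:
            return f"< {1.0 / self.n_valid:.2g}"
        return f"{self.p_value:.4g}"

    def null_quantiles(self, qs=(0.025, 0.25, 0.5, 0.75, 0.975)) -> dict[str, float]:
        if self.n_valid == 0:
            return {f"q{q}": float("nan") for q in qs}
        return {f"q{q}": float(np.quantile(self.null_stats, q)) for q in qs}

    def to_dict(self, include_null_stats: bool = False) -> dict:
        d = {
            "statistic_name": self.statistic_name,
            "observed": float(self.observed),
            "p_value": float(self.p_value),
            "sidedness": self.sidedness,
            "n_iter": int(self.n_iter),
            "n_valid": int(self.n_valid),
            "seed": int(self.seed),
            "null_quantiles": self.null_quantiles(),
        }
        if include_null_stats:
            d["null_stats"] = [float(x) for x in self.null_stats]
        return d


# ---------------------------------------------------------------------------
# chain estimation and simulation


def estimate_transitions(states: StateSeries) -> TransitionProbs:
    """Empirical switching probabilities over consecutive sample pairs.

    Counting is exact integer arithmetic; the age gap between neighbours
    is irrelevant.  A state never observed as a source gets switching
    probability 0 with a warning — the chain can then never enter the
    other state.
    """
    if len(states) < 2:
        raise ValueError("need >= 2 samples to estimate transition probabilities")
    s = states.laminated
    src, dst = s[:-1], s[1:]
    from_N = int((~src).sum())
    from_L = int(src.sum())
    n_NL = int((~src & dst).sum())
    n_LN = int((src & ~dst).sum())
    if from_N == 0:
        warnings.warn("no transitions from nonlaminated observed; p_NL set to 0",
                      stacklevel=2)
    if from_L == 0:
        warnings.warn("no transitions from laminated observed; p_LN set to 0",
                      stacklevel=2)
    return TransitionProbs(
        p_NL=n_NL / from_N if from_N else 0.0,
        p_LN=n_LN / from_L if from_L else 0.0,
        n_transitions_from_N=from_N,
        n_transitions_from_L=from_L,
    )


def _simulate_matrix(
    n_iter: int, n: int, probs: TransitionProbs, initial_laminated: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_iter, n) boolean matrix of chains, vectorized across iterations."""
    out = np.empty((n_iter, n), dtype=bool)
    out[:, 0] = initial_laminated
    if n > 1:
        u = rng.random((n_iter, n - 1))
        for t in range(1, n):
            prev = out[:, t - 1]
            p_switch = np.where(prev, probs.p_LN, probs.p_NL)
            out[:, t] = prev ^ (u[:, t - 1] < p_switch)
    return out


def simulate_states(
    n: int,
    probs: TransitionProbs,
    initial_laminated: bool = False,
    rng_seed: int | np.random.Generator = 0,
    ages=None,
) -> StateSeries:
    """Draw one chain realisation; bit-reproducible for a given seed.

    ``ages`` defaults to 0..n-1; pass the observed sample ages to label a
    real record's positions.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    lam = _simulate_matrix(1, n, probs, initial_laminated, rng)[0]
    if ages is None:
        ages = np.arange(n, dtype=float)
    return StateSeries(ages=ages, laminated=lam)


# ---------------------------------------------------------------------------
# p-values


def p_value(observed: float, null_stats, sidedness: str = TWO_SIDED) -> float:
    """Proportion of null statistics as extreme as or more extreme than observed.

    Two-sided mode measures extremity as absolute deviation from the mean
    of the null statistics; one-sided mode takes the tail on the side of
    the observed deviation.  Ties (equality) count as extreme, so p is
    never 0 when the observed value is itself attainable under the null.
    """
    null = np.asarray(null_stats, dtype=float)
    if null.size == 0:
        raise ValueError("null_stats must be nonempty")
    if sidedness not in _SIDEDNESS:
        raise ValueError(f"sidedness must be one of {_SIDEDNESS}")
    if sidedness == TWO_SIDED:
        m = null.mean()
        return float(np.mean(np.abs(null - m) >= abs(observed - m)))
    m = null.mean()
    if observed >= m:
        return float(np.mean(null >= observed))
    return float(np.mean(null <= observed))


# ---------------------------------------------------------------------------
# the three test designs


def _check_alignment(values: ProxySeries, states: StateSeries) -> None:
    if len(values) != len(states) or not np.array_equal(values.ages, states.ages):
        raise ValueError("values and states must share the same sample ages")


def _run_mc(
    name: str,
    observed: float,
    values: np.ndarray,
    states: StateSeries,
    stat_kind: str,
    n_iter: int,
    seed: int,
    sidedness: str,
    probs: TransitionProbs | None = None,
) -> MCTestResult:
    """Shared engine: fit the chain, simulate labellings, recompute the statistic.

    ``stat_kind``: 'diff' needs both groups nonempty, 'during' needs a
    nonempty laminated group.  Iterations with an undefined statistic are
    discarded and surfaced through ``n_valid``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if probs is None:
        probs = estimate_transitions(states)
    rng = np.random.default_rng(seed)
    n = len(states)
    finite = np.isfinite(values)
    v0 = np.where(finite, values, 0.0)
    initial = bool(states.laminated[0])

    null_list = []
    n_discarded = 0
    done = 0
    while done < n_iter:
        m = min(_CHUNK, n_iter - done)
        sims = _simulate_matrix(m, n, probs, initial, rng)
        lam = sims & finite
        non = ~sims & finite
        cnt_l = lam.sum(axis=1)
        cnt_n = non.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_l = (lam * v0).sum(axis=1) / cnt_l
            mean_n = (non * v0).sum(axis=1) / cnt_n
        if stat_kind == "diff":
            ok = (cnt_l > 0) & (cnt_n > 0)
            stats = mean_l - mean_n
        else:  # 'during'
            ok = cnt_l > 0
            stats = mean_l
        null_list.append(stats[ok])
        n_discarded += int(m - ok.sum())
        done += m

    null = np.concatenate(null_list) if null_list else np.empty(0)
    n_valid = int(null.size)
    if n_discarded:
        warnings.warn(
            f"{name}: discarded {n_discarded} of {n_iter} iterations with an "
            "undefined statistic",
            stacklevel=3,
        )
    if n_valid == 0 or not np.isfinite(observed):
        return MCTestResult(
            statistic_name=name, observed=float(observed), null_stats=null,
            n_iter=n_iter, n_valid=0, p_value=float("nan"),
            sidedness=sidedness, seed=seed,
        )
    return MCTestResult(
        statistic_name=name, observed=float(observed), null_stats=null,
        n_iter=n_iter, n_valid=n_valid,
        p_value=p_value(observed, null, sidedness),
        sidedness=sidedness, seed=seed,
    )


def mc_test_mean_difference(
    values: ProxySeries,
    states: StateSeries,
    n_iter: int = 10_000,
    seed: int = 0,
    sidedness: str = TWO_SIDED,
    probs: TransitionProbs | None = None,
) -> MCTestResult:
    """Test: proxy mean in laminated minus nonlaminated samples.

    Both observed groups must contain at least one usable value.
    ``probs`` overrides the chain fitted from the observed states (mainly
    for cross-checks against exact enumeration).
    """
    _check_alignment(values, states)
    v = values.values
    ok = np.isfinite(v)
    lam = states.laminated & ok
    non = ~states.laminated & ok
    if not lam.any() or not non.any():
        raise ValueError(
            "observed mean difference undefined: a group has no usable values"
        )
    observed = v[lam].mean() - v[non].mean()
    return _run_mc(
        f"{values.name}_mean_difference", observed, v, states,
        "diff", n_iter, seed, sidedness, probs,
    )


def mc_test_state_proportion(
    climate: ClimateSeries,
    states: StateSeries,
    target: ClimateLabel,
    n_iter: int = 10_000,
    seed: int = 0,
    sidedness: str = TWO_SIDED,
    probs: TransitionProbs | None = None,
) -> MCTestResult:
    """Test: proportion of laminated samples carrying a climate label.

    E.g. the fraction of laminated samples whose δ18O classifies as
    Glacial.  The indicator of the target label is averaged over the
    laminated group, observed and under every simulated labelling.
    """
    if len(climate) != len(states) or not np.array_equal(climate.ages, states.ages):
        raise ValueError("climate and states must share the same sample ages")
    if not states.laminated.any():
        raise ValueError("no laminated samples observed")
    target = ClimateLabel(target)
    ind = np.array([lab == target for lab in climate.labels], dtype=float)
    observed = ind[states.laminated].mean()
    return _run_mc(
        f"proportion_laminated_{target.value.lower()}", observed, ind, states,
        "during", n_iter, seed, sidedness, probs,
    )


def mc_test_mean_during_events(
    values: ProxySeries,
    states: StateSeries,
    n_iter: int = 10_000,
    seed: int = 0,
    sidedness: str = TWO_SIDED,
    probs: TransitionProbs | None = None,
) -> MCTestResult:
    """Test: proxy mean over laminated samples only (e.g. mean RSL)."""
    _check_alignment(values, states)
    v = values.values
    lam = states.laminated & np.isfinite(v)
    if not lam.any():
        raise ValueError(
            "observed statistic undefined: no usable laminated values"
        )
    observed = v[lam].mean()
    return _run_mc(
        f"{values.name}_mean_during_laminations", observed, v, states,
        "during", n_iter, seed, sidedness, probs,
    )
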