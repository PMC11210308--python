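"""Readers, writers, configuration and the full analysis battery.

The sample-table dialect is a plain UTF-8 CSV with a header: ``age_ka``,
optional ``depth_m``, one column per proxy, and an optional ``laminated``
0/1 column.  The interval-table dialect has columns ``label``,
``start_age_ka``, ``end_age_ka``.  ``run_full_analysis`` chains climate
classification, z-scores and the Monte Carlo battery and returns a
serializable bundle; ``write_report`` emits a JSON summary plus
histogram-ready per-test null-statistic CSVs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .climate import ClimateLabel, classify_samples, climate_summary, interval_climate
from .mctest import (
    TWO_SIDED,
    mc_test_mean_difference,
    mc_test_mean_during_events,
    mc_test_state_proportion,
)
from .series import (
    IntervalTable,
    LaminatedInterval,
    ProxySeries,
    StateSeries,
    states_from_intervals,
)
from .zscore import compute_zscores, detrend_normalize, zscore_group_comparison

__all__ = [
    "AnalysisConfig",
    "load_sample_table",
    "load_interval_table",
    "write_sample_table",
    "write_interval_table",
    "spawn_seeds",
    "run_full_analysis",
    "write_report",
]

log = logging.getLogger("lamstats")

_RESERVED = {"age_ka", "depth_m", "laminated"}


def load_sample_table(path) -> tuple[dict[str, ProxySeries], StateSeries | None]:
    """Read the sample-table CSV into one ProxySeries per proxy column.

    Rows must be sortable by strictly increasing ``age_ka``; duplicate
    ages and unparseable age cells are rejected with 1-based file line
    numbers.  Blank proxy cells become missing values.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "age_ka" not in df.columns:
        raise ValueError(f"{path}: missing required 'age_ka' column")
    ages_raw = pd.to_numeric(df["age_ka"], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(ages_raw.to_numpy()))
    if bad.size:
        lines = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
        raise ValueError(f"{path}: unparseable age_ka at line(s) {lines}")
    order = np.argsort(ages_raw.to_numpy(), kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    ages = df["age_ka"].to_numpy(dtype=float)
    dup = np.flatnonzero(np.diff(ages) == 0)
    if dup.size:
        lines = ", ".join(str(int(order[i + 1]) + 2) for i in dup[:5])
        raise ValueError(f"{path}: duplicated age_ka at line(s) {lines}")

    depths = df["depth_m"].to_numpy(dtype=float) if "depth_m" in df.columns else None
    proxies: dict[str, ProxySeries] = {}
    for col in df.columns:
        if col in _RESERVED:
            continue
        proxies[col] = ProxySeries(
            name=col, ages=ages,
            values=pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float),
            depths=depths,
        )
    states = None
    if "laminated" in df.columns:
        states = StateSeries(
            ages=ages, laminated=df["laminated"].to_numpy(dtype=float) > 0.5
        )
    return proxies, states


def load_interval_table(path) -> IntervalTable:
    df = pd.read_csv(path)
    needed = {"label", "start_age_ka", "end_age_ka"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: interval table needs columns {sorted(needed)}")
    return IntervalTable(tuple(
        LaminatedInterval(str(r.label), float(r.start_age_ka), float(r.end_age_ka))
        for r in df.itertuples(index=False)
    ))


def write_sample_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_interval_table(intervals: IntervalTable, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    intervals.to_frame().to_csv(path, index=False)


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive n independent per-test integer seeds from one master seed."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of the full battery; defaults follow the published design."""

    d18O_proxy: str = "d18O"
    d15N_proxy: str = "d15N"
    rsl_proxy: str | None = "rsl"
    mean_difference_proxies: tuple = ()
    smooth_k: int = 3
    step_ka: float = 1.0
    climate_window_ka: float = 100.0
    z_window_ka: float = 100.0
    z_threshold: float = 1.645
    n_iter: int = 10_000
    seed: int = 0
    sidedness: str = TWO_SIDED

    def __post_init__(self):
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "mean_difference_proxies" in raw:
            raw["mean_difference_proxies"] = tuple(raw["mean_difference_proxies"])
        return cls(**raw)


def run_full_analysis(
    proxies: dict[str, ProxySeries],
    states: StateSeries | None,
    intervals: IntervalTable | None,
    config: AnalysisConfig = AnalysisConfig(),
) -> dict:
    """Run the whole statistical battery and return a serializable bundle.

    Stages: climate classification from δ18O; interval climate typing;
    δ15N detrend/normalize + moving-window z-scores; Monte Carlo tests
    for glacial and interglacial proportions, each configured proxy's
    laminated/nonlaminated mean difference, the z-score mean difference,
    and mean RSL during laminations.  Per-test seeds are spawned
    deterministically from ``config.seed``.  Any stage failure raises
    with the stage named.
    """
    if states is None and intervals is None:
        raise ValueError("either a laminated column or an interval table is required")

    def stage(name):
        log.info("stage: %s", name)
        return name

    bundle: dict = {
        "config": {
            "smooth_k": config.smooth_k,
            "step_ka": config.step_ka,
            "climate_window_ka": config.climate_window_ka,
            "z_window_ka": config.z_window_ka,
            "z_threshold": config.z_threshold,
            "n_iter": config.n_iter,
            "seed": config.seed,
            "sidedness": config.sidedness,
        },
    }
    current = "setup"
    try:
        current = stage("states")
        if states is None:
            any_proxy = next(iter(proxies.values()))
            states = states_from_intervals(any_proxy.ages, intervals)

        current = stage("climate_classification")
        if config.d18O_proxy not in proxies:
            raise ValueError(f"proxy {config.d18O_proxy!r} not in input")
        climate = classify_samples(
            proxies[config.d18O_proxy],
            smooth_k=config.smooth_k,
            step_ka=config.step_ka,
            window_ka=config.climate_window_ka,
        )
        bundle["climate"] = {
            "age_ka": climate.ages.tolist(),
            "d18O": _jlist(climate.d18O),
            "baseline_mean": _jlist(climate.baseline_mean),
            "baseline_sd": _jlist(climate.baseline_sd),
            "label": [lab.value for lab in climate.labels],
        }
        if intervals is not None:
            current = stage("interval_climate")
            per_iv = interval_climate(intervals, climate)
            bundle["interval_climate"] = {
                k: sorted(lab.value for lab in v) for k, v in per_iv.items()
            }
            bundle["climate_summary"] = climate_summary(intervals, climate)

        current = stage("zscores")
        zs = None
        if config.d15N_proxy and config.d15N_proxy in proxies:
            chi = detrend_normalize(proxies[config.d15N_proxy])
            zs = compute_zscores(chi, window_ka=config.z_window_ka,
                                 threshold=config.z_threshold)
            m_lam, m_non, diff = zscore_group_comparison(zs, states)
            bundle["zscore"] = {
                "age_ka": zs.ages.tolist(),
                "chi": _jlist(zs.chi),
                "running_mean": _jlist(zs.running_mean),
                "running_sd": _jlist(zs.running_sd),
                "z": _jlist(zs.z),
                "significant": zs.significant.astype(int).tolist(),
                "mean_laminated": _jf(m_lam),
                "mean_nonlaminated": _jf(m_non),
                "difference": _jf(diff),
            }

        current = stage("monte_carlo_battery")
        tests = []
        n_tests = 3 + len(config.mean_difference_proxies) + (zs is not None) \
            + (config.rsl_proxy is not None and config.rsl_proxy in proxies)
        seeds = iter(spawn_seeds(config.seed, n_tests))
        tests.append(mc_test_state_proportion(
            climate, states, ClimateLabel.GLACIAL,
            n_iter=config.n_iter, seed=next(seeds), sidedness=config.sidedness))
        tests.append(mc_test_state_proportion(
            climate, states, ClimateLabel.INTERGLACIAL,
            n_iter=config.n_iter, seed=next(seeds), sidedness=config.sidedness))
        for proxy in config.mean_difference_proxies:
            if proxy not in proxies:
                raise ValueError(f"proxy {proxy!r} not in input")
            tests.append(mc_test_mean_difference(
                proxies[proxy], states,
                n_iter=config.n_iter, seed=next(seeds), sidedness=config.sidedness))
        if zs is not None:
            tests.append(mc_test_mean_difference(
                zs.as_proxy(name=f"{config.d15N_proxy}_z"), states,
                n_iter=config.n_iter, seed=next(seeds), sidedness=config.sidedness))
        if config.rsl_proxy is not None and config.rsl_proxy in proxies:
            tests.append(mc_test_mean_during_events(
                proxies[config.rsl_proxy], states,
                n_iter=config.n_iter, seed=next(seeds), sidedness=config.sidedness))
        # remaining spawned seed (if any) belongs to a skipped optional test
        for t in tests:
            log.info("test %s: n_valid=%d of %d", t.statistic_name,
                     t.n_valid, t.n_iter)
        bundle["tests"] = [t.to_dict(include_null_stats=True) for t in tests]
    except Exception as exc:
        raise RuntimeError(f"analysis stage {current!r} failed: {exc}") from exc
    return bundle


def _jf(x) -> float | None:
    """JSON-safe float: NaN/inf become null."""
    x = float(x)
    return x if np.isfinite(x) else None


def _jlist(arr) -> list:
    return [_jf(x) for x in np.asarray(arr, dtype=float)]


def write_report(bundle: dict, out_dir) -> list[Path]:
    """Serialize a bundle: summary JSON, per-sample CSVs, per-test null CSVs.

    File contents are deterministic (sorted keys, fixed column order) so
    identical bundles produce identical bytes.  Returns written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    summary = {k: v for k, v in bundle.items() if k not in ("climate", "zscore")}
    summary["tests"] = [
        {k: v for k, v in t.items() if k != "null_stats"}
        for t in bundle.get("tests", [])
    ]
    p = out / "summary.json"
    p.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n",
                 encoding="utf-8")
    written.append(p)

    if "climate" in bundle:
        p = out / "climate_samples.csv"
        pd.DataFrame(bundle["climate"]).to_csv(p, index=False)
        written.append(p)
    if "zscore" in bundle:
        cols = ["age_ka", "chi", "running_mean", "running_sd", "z", "significant"]
        p = out / "zscore_samples.csv"
        pd.DataFrame({c: bundle["zscore"][c] for c in cols}).to_csv(p, index=False)
        written.append(p)
    for t in bundle.get("tests", []):
        if "null_stats" not in t:
            continue
        p = out / f"null_stats_{t['statistic_name']}.csv"
        pd.DataFrame({"null_stat": t["null_stats"]}).to_csv(p, index=False)
        written.append(p)
    return written
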