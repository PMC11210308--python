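# lamstats

Randomization statistics for laminated (hypoxic) sediment-core records.

Laminated intervals in marine sediment cores record episodes of bottom-water
hypoxia: the fine layering survives only when oxygen is too low for
burrowing macrofauna. Whether those episodes line up with particular climate
states, productivity regimes, nitrate-utilization peaks or sea-level stands
is a statistical question that ordinary two-sample tests cannot answer —
core records are strongly autocorrelated and unevenly sampled, so their
samples are nothing like independent draws. `lamstats` implements the
Markov-chain randomization approach for exactly this setting, together with
the climate classification and moving-window z-scoring that feed it, and a
synthetic multi-proxy core generator so the whole pipeline runs with no
external data.

## The statistics

**Climate classification.** With benthic foraminiferal δ¹⁸O as the climate
proxy (higher = more global ice = more glacial), a sample is *Glacial* if
its raw δ¹⁸O lies more than 1σ above a 100-ka moving window of a
three-point running mean interpolated to a 1-ka grid, *Interglacial* if
more than 1σ below, and *Intermediate* otherwise. Laminated intervals are
climate-typed by the set of labels their samples carry.

**Nitrate-utilization peaks.** Bulk δ¹⁵N is detrended (OLS in age) and
normalized to unit residual variance, giving χ; then

    z_t = (χ_t − x̄_t) / σ_t

with x̄_t, σ_t the mean and n−1 SD of χ over a centered 100-ka window.
z ≥ 1.645 flags a one-sided significantly high value at the 5% level.

**Randomization tests.** For each hypothesis the proxy values stay fixed
while the binary lamination labelling is redrawn 10,000 times from a
two-state Markov chain whose switching probabilities p_NL, p_LN are the
empirical consecutive-sample switch rates of the observed record — the
null therefore preserves the run-length structure of the event series.
Three statistics are supported: the laminated-minus-nonlaminated mean of a
proxy, the proportion of laminated samples carrying a climate label, and
the proxy mean during laminations only (used for sea level). The p-value
is the proportion of simulated statistics at least as extreme as the
observed one (by default, deviation from the null mean; one-sided
available), with ties counted as extreme and undefined iterations
discarded and reported.

## Worked example

```python
import lamstats as ls
from lamstats.climate import ClimateLabel

core = ls.generate_core(ls.CoreConfig(seed=7))   # ~1200-ka synthetic core
climate = ls.classify_samples(core.proxy("d18O"))
print(ls.climate_summary(core.intervals, climate))
res = ls.mc_test_state_proportion(climate, core.states,
                                  ClimateLabel.INTERGLACIAL,
                                  n_iter=10_000, seed=123)
print(res.observed, res.p_value_display())
```

On this core (2093 samples, 21 laminated intervals) the climate summary
reports 18 of 21 intervals with no glacial samples, and the interglacial
proportion test gives an observed proportion of 0.43 with p ≈ 0.001 — the
laminations sit in interglacial-labelled samples far more often than the
autocorrelation-preserving null predicts, which is the planted behaviour
of the generator's climate coupling. The scripts in `examples/` walk
through each capability (simulation, classification, z-scores, the test
battery, and full CSV-in/report-out runs) and print the numbers they
compute; a thin CLI (`lamstats simulate|classify|zscore|mctest|analyze|report`)
wraps the same functions for shell use.

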