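# Methods

## The inferential problem

A lamination record is a binary event series observed at the sample ages
of a sediment core: each sample is laminated (deposited under hypoxia)
or not. Hypotheses of the form "laminated samples have higher Si/Ti",
"laminations avoid glacial climates" or "sea level is high during
laminations" compare a statistic between the two groups. Classical
two-sample t and chi-square machinery assumes independent observations;
core records violate this twice over — consecutive samples are strongly
autocorrelated, and sampling density varies with lithology (laminated
sections are typically sampled more finely). The randomization approach
implemented here replaces the analytic null with a simulated one that
preserves the event series' serial structure.

## The Markov null

From the observed labelling, `estimate_transitions` counts state
switches over consecutive sample pairs and forms the empirical switching
probabilities p_NL (nonlaminated→laminated) and p_LN (the reverse). Age
gaps between neighbours are deliberately ignored: the chain steps per
sample, exactly as the labels were recorded. Each of the 10,000 null
iterations redraws the labelling from this chain, started at the
observed first state, and recomputes the test statistic on the fixed
proxy values. Geometric run lengths with the fitted switch rates
reproduce the observed record's run-length scale, so the null embodies
"laminations occur in autocorrelated episodes of the observed
persistence, placed without regard to the proxy".

The p-value is the proportion of simulated statistics as extreme as or
more extreme than the observed one, ties included. "Extreme" defaults to
absolute deviation from the null-distribution mean (a symmetric,
two-sided reading); a one-sided mode (tail on the observed side) is
available, and both are recorded in every result. The plain proportion
is reported (no +1 correction); a Monte Carlo zero is displayed as
"< 1/n_valid" to flag resolution. Iterations whose statistic is
undefined — an empty group under the 'diff' statistic, no laminated
samples under the 'during' statistics — are discarded, counted in
`n_valid`, and warned about; if none remain the result is flagged
invalid with a NaN p-value rather than imputed.

Known behaviour of this design, measured by the calibration harness
(`lamstats.experiments`):

* With the lamination sequence exactly first-order Markov in sample
  index, all three designs hold their nominal level: across 200 null
  cores the rejection rates at α = 0.05 fall between 0.01 and 0.06
  (inside the 99% binomial band), and replicate p-values are
  approximately uniform (KS distance tolerance 0.15, which absorbs the
  mild conservativeness of tie-counting and of plugging in estimated
  switch rates).
* Densified sampling inside laminated intervals breaks the
  Markov-in-index assumption: laminated runs become long in samples but
  short in time, and for value series with long temporal memory (the
  glacial/interglacial indicator especially) the proportion-type test's
  type-I error inflates to roughly 0.13 at α = 0.05 under the
  generator's default 0.25-ka laminated spacing. This limitation is
  inherent to fitting a per-sample chain to a record whose sampling
  density is state-dependent; analyses of strongly densified records
  should read proportion-test p-values near the threshold with caution.
  The calibration experiment therefore uses uniform ~1-ka spacing
  (~1200 samples), which is also the regime where the per-sample chain
  is the exactly correct null.

## Climate classification

Pipeline: three-point centered running mean on the raw δ¹⁸O samples →
linear interpolation onto a uniform 1-ka grid → closed, centered 100-ka
window mean and n−1 SD on the grid → baselines interpolated back to the
sample ages (constant beyond the grid ends). Each sample's *raw* δ¹⁸O is
compared against mean ± 1σ; comparing the smoothed value instead is
exposed as `compare_smoothed` but off by default, since smoothing the
test value as well would double-smooth. Smoothing precedes gridding
because the three-point mean is defined on the measurement structure,
while the uniform grid exists so the window SD reflects orbital-band
variability rather than sampling density. A missing or zero window SD
yields Intermediate, never an exception: a flat window carries no
glacial/interglacial information. The rule is translation-invariant and
swaps Glacial↔Interglacial under sign flip; both properties are tested,
and the whole pipeline is checked sample-by-sample against an
independent loop-based enumeration oracle.

## δ¹⁵N z-scores

"Detrended and normalized" is implemented as ordinary least-squares
linear detrending over the full record followed by division by the
residuals' n−1 standard deviation; both steps are plain function
composition and other normalizations can be substituted by skipping
`detrend_normalize`. Window statistics are centered, closed and
age-based (matching the climate classifier); windows with fewer than two
usable values, or zero SD, give a missing z that is never significant.
Significance is one-sided high only (z ≥ 1.645, the standard-normal
upper 5% point to three decimals): low excursions are reported but not
flagged. Because the 100-ka window is wide relative to brief laminated
intervals, short genuine peaks can fail to reach the threshold; the
per-sample window statistics are stored in the result so this dilution
is auditable.

## Synthetic cores

`generate_core` emulates the statistical structure the analysis assumes,
not sediment physics:

* **Ages** — increments of 1.0 ka ± 30% jitter over 1200 ka; inside
  laminated intervals extra samples at 0.25-ka spacing (only when that
  is strictly finer than the base spacing), mirroring fixed-depth
  sampling of finely layered sections.
* **δ¹⁸O** — mean 4.0‰ plus 41-ka and 100-ka sinusoids of amplitude
  0.5‰ and AR(1) noise (coefficient 0.7, marginal SD 0.15‰); higher =
  more glacial.
* **Lamination chain** — base switching probabilities p_NL = 0.015,
  p_LN = 0.12, chosen so a 1200-ka core carries on the order of twenty
  laminated intervals ranging from sub-ka events to multi-10-ka states
  at ~15% laminated time, the regime the method targets. Climate
  coupling (default 1.0) shifts the log-odds of being laminated next by
  the standardized *negative* δ¹⁸O anomaly, so laminations favour
  interglacial conditions while the state process stays within the
  Markov family the null fits. Coupling acts on the switching odds, not
  by relabelling, precisely so that the alternative differs from the
  null only in its climate linkage.
* **Covariates** — AR(1) noise (coefficient 0.5, SD 1) plus a
  laminated-state mean shift per proxy; defaults follow the
  productivity signature of laminated sediments (Si/Ti +2 SD, Fe/Ti
  +1 SD, wt% N +0.5 SD, GRA −1.5 SD, NGR −1.5 SD).
* **δ¹⁵N** — baseline 6‰, slight linear trend, AR(1) noise SD 0.3‰, +1‰
  during laminated samples.
* **Sea level** — mean −45 m, +30 m per SD of the negative δ¹⁸O anomaly
  (anticorrelated with ice volume), white noise SD 5 m.

`CoreConfig.null()` switches off the coupling and every state effect,
making states and proxies independent by construction — the exact null
used for calibration. What the generator does *not* emulate: age-model
error, nonstationarity of cycle period (mid-Pleistocene-transition-style
regime shifts), measurement noise heteroscedasticity, or diagenesis.
Passing calibration and power tests on these cores therefore shows the
machinery is correct under its stated assumptions, not that those
assumptions hold for any particular real core.

## Experiment sizes and numerical choices

The calibration experiment uses 200 replicate null cores (~1200 samples)
and the power experiment 100 replicates (~1000 samples, planted 2-SD
Si/Ti shift), with 500 Monte Carlo iterations per test inside the
replicates — the α = 0.05 decision needs only ~1/500 p-resolution, and
headline analyses still default to 10,000 iterations. Windows are closed
on both ends; running-mean edge windows truncate to the available
points; sample SDs use n−1 throughout; missing values are NaN, excluded
per window and never imputed; elemental ratios with nonpositive or
missing denominators are missing, not errors. Interval endpoints are
closed (a sample at a described boundary belongs to the interval). Each
test draws from its own PCG64 stream whose integer seed is recorded in
the result; the analysis battery spawns per-test seeds from one master
seed via `numpy.random.SeedSequence`, so the full report is
byte-reproducible.

## Limitations

* The per-sample chain ignores age gaps; a per-ka (continuous-time)
  variant is out of scope, and state-dependent sampling density
  miscalibrates proportion-type tests as quantified above.
* Transition probabilities are plugged in as point estimates; records
  with very few laminated runs estimate p_LN poorly, widening the gap
  between nominal and actual level.
* No multiple-testing correction is applied across the proxy battery;
  consumers testing many proxies should adjust downstream.
* The two-sided "deviation from null mean" reading of extremity is one
  of several defensible conventions; the one-sided mode is provided and
  the choice is always serialized with the result.
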