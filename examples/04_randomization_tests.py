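"""Markov-chain Monte Carlo randomization tests on one core.

Each test keeps the proxy values fixed and redraws the lamination
labelling 10,000 times from a two-state Markov chain fitted to the
observed consecutive-sample switches, which preserves the event series'
autocorrelation under the null of no association.  The p-value is the
proportion of simulated statistics at least as extreme (in deviation
from the null mean) as the observed one.
"""

import warnings

import lamstats as ls
from lamstats.climate import ClimateLabel

core = ls.generate_core(ls.CoreConfig(seed=7))
states = core.states
climate = ls.classify_samples(core.proxy("d18O"))
seeds = ls.spawn_seeds(123, 4)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    results = [
        ls.mc_test_state_proportion(climate, states,
                                    ClimateLabel.INTERGLACIAL,
                                    n_iter=10_000, seed=seeds[0]),
        ls.mc_test_state_proportion(climate, states, ClimateLabel.GLACIAL,
                                    n_iter=10_000, seed=seeds[1]),
        ls.mc_test_mean_difference(core.proxy("si_ti"), states,
                                   n_iter=10_000, seed=seeds[2]),
        ls.mc_test_mean_during_events(core.proxy("rsl"), states,
                                      n_iter=10_000, seed=seeds[3]),
    ]

for r in results:
    print(f"{r.statistic_name:42s} observed={r.observed:+9.3f} "
          f"p={r.p_value_display():>9s} (n_valid={r.n_valid})")

print("\nSmall p-values throughout reproduce the pattern the method is "
      "built to detect: the interglacial proportion is significantly HIGH "
      "and the glacial proportion significantly LOW (its observed value "
      "sits far below the null mean), while laminations coincide with "
      "high Si/Ti (productivity) and high (less negative) sea level.")
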