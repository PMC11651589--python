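"""Fit the main model: conditional logistic regression on matched sets.

Builds time-stratified matched sets (same weekday, same month referents),
attaches the lag 0-2 mean PM2.5 and lagged temperatures, and maximises
the conditional likelihood with the 12-column temperature cross-basis and
a holiday indicator as covariates.
"""

import numpy as np

from ccburden import SynthConfig, build_design, build_matched_sets, fit, generate, or_per_increment

config = SynthConfig(seed=1)
panel, cases = generate(config)

sets, dropped = build_matched_sets(cases, panel)
print(f"matched sets: {sets['set_id'].nunique()} "
      f"({len(sets)} member days; dropped {dropped})")

dm = build_design(sets)  # linear PM + temperature cross-basis + holiday
result = fit(dm)
print(f"converged in {result.n_iter} Newton iterations "
      f"(gradient norm {result.grad_norm:.1e})")

or10 = or_per_increment(result)
print(f"\nOR per 10 ug/m3: {or10['or']:.3f} "
      f"(95% CI {or10['ci_low']:.3f}-{or10['ci_high']:.3f})")
print(f"generating truth: {np.exp(10 * config.true_log_or_per_10 / 10):.3f}")
print("The estimate is the within-month, within-weekday association; at "
      "~2,800 cases a single run scatters around the truth by its CI width.")
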