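"""Subgroup analyses with Wald contrasts.

Rebuilds the case-crossover dataset per subgroup level (sex, season,
season x age) and refits; pairwise Wald z-tests ask whether two subgroup
log-ORs differ more than their pooled standard error allows.
"""

from ccburden import SynthConfig, generate, pairwise_wald, stratified_fits

config = SynthConfig(seed=1)
panel, cases = generate(config)

for factor in ("sex", "season", ("season", "age_group")):
    label = factor if isinstance(factor, str) else " x ".join(factor)
    results = stratified_fits(cases, panel, factor)
    print(f"== {label}")
    for level, r in results.items():
        if r.or_per_10 is None:
            print(f"  {level:12s} n={r.n_cases:5d}  (no informative sets)")
            continue
        o = r.or_per_10
        print(f"  {level:12s} n={r.n_cases:5d}  OR/10 {o['or']:.3f} "
              f"({o['ci_low']:.3f}-{o['ci_high']:.3f})")
    wald = pairwise_wald(results)
    for _, row in wald.iterrows():
        print(f"  Wald {row['level_1']} vs {row['level_2']}: "
              f"z={row['z']:.2f}, p={row['p']:.3f}")
    print()

print("The generator gives every subgroup the same true effect, so "
      "contrasts should be non-significant up to the 5% false-positive rate.")
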