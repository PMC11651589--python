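"""One-call pipeline with a sensitivity sweep over model variants.

Runs design -> fit -> subgroups -> burden from a single RunConfig and
refits the main estimate under alternative exposure lags and temperature
adjustments (single lags, longer moving averages, temperature lag 3/7,
spline df 3/5).
"""

from ccburden import RunConfig, run_pipeline

config = RunConfig(
    out_dir="scratch/example_run",
    synth={"n_districts": 10, "start": "2015-01-01", "end": "2017-12-31",
           "baseline_rate": 0.3},
    seed=1,
    n_sim=500,
    subgroups=["sex", "season"],
    sensitivity={
        "exposure_lags": ["single:0", "single:1", "ma:0-1", "ma:0-3"],
        "temp_lags": [2, 3, 7],
        "temp_df": [3, 4, 5],
    },
)
bundle = run_pipeline(config)

o = bundle["fit"]["or_per_10"]
print(f"main model OR/10: {o['or']:.3f} ({o['ci_low']:.3f}-{o['ci_high']:.3f})")
print(f"sensitivity variants fitted: {len(bundle['sensitivity'])}")
for v in bundle["sensitivity"][:6]:
    print(f"  lag={v['lag']:9s} temp_lags={v['temp_lags']} df={v['temp_df']}: "
          f"OR/10 {v['or']:.3f}")
print("  ...")
print("\nA robust association keeps a similar OR across variants; results "
      "and provenance were written to scratch/example_run/results.json.")
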