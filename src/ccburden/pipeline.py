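"""Pipeline driver: design -> basis -> fit -> subgroups -> burden.

Reads case and panel CSVs (or generates synthetic ones), runs the full
case-crossover analysis described by a :class:`~ccburden.config.RunConfig`,
and writes JSON/CSV results plus a provenance block (config hash, seed,
package version) and stage-level counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .burden import Scenario, attribution_series, mc_confidence
from .clogit import build_design, fit, or_per_increment
from .config import RunConfig, temp_spec_from
from .descriptives import summarize
from .design import LagSpec, build_matched_sets
from .subgroup import pairwise_wald, stratified_fits
from .synth import SynthConfig, generate

__all__ = ["run_pipeline", "read_cases", "read_panel"]

logger = logging.getLogger(__name__)


def read_panel(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"exposure panel not found: {path}")
    panel = pd.read_csv(path, parse_dates=["date"])
    panel["holiday"] = panel["holiday"].astype(bool)
    return panel


def read_cases(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"case records not found: {path}")
    cases = pd.read_csv(path, parse_dates=["event_date"])
    for col in ("urban", "grdp_high"):
        if col in cases.columns:
            cases[col] = cases[col].astype(bool)
    return cases


def _scenarios(config: RunConfig) -> list[Scenario]:
    return [Scenario(**s) for s in config.scenarios]


def _fit_main(cases, panel, lag_spec, temp_spec, holiday):
    sets, dropped = build_matched_sets(
        cases, panel, lag_spec, temp_lags=temp_spec.lag_range[1]
    )
    dm = build_design(sets, pm="linear", temp=temp_spec, holiday=holiday)
    res = fit(dm)
    return sets, dm, res, dropped


def run_pipeline(config: RunConfig, cases: pd.DataFrame | None = None,
                 panel: pd.DataFrame | None = None) -> dict:
    """Execute the full analysis; returns (and writes) the result bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cases is None or panel is None:
        if config.cases_path and config.panel_path:
            cases = read_cases(config.cases_path)
            panel = read_panel(config.panel_path)
        elif config.synth is not None:
            synth_cfg = SynthConfig(**{"seed": config.seed, **config.synth})
            panel, cases = generate(synth_cfg)
            logger.info("generated synthetic data: %d cases", len(cases))
        else:
            raise ValueError("config provides neither data paths nor synth settings")
    logger.info("cases read: %d; panel rows: %d", len(cases), len(panel))

    lag_spec = config.lag_spec()
    temp_spec = config.temp_spec()
    sets, dm, main_fit, dropped = _fit_main(
        cases, panel, lag_spec, temp_spec, config.holiday
    )
    logger.info(
        "matched sets built: %d (dropped %s); fit converged=%s in %d iterations",
        dm.n_sets, dropped, main_fit.converged, main_fit.n_iter,
    )
    main_or = or_per_increment(main_fit)

    subgroups = {}
    for factor in config.subgroups:
        key = factor if isinstance(factor, str) else ":".join(factor)
        factor_arg = factor if isinstance(factor, str) else tuple(factor)
        levels = stratified_fits(
            cases, panel, factor_arg, lag_spec=lag_spec, temp=temp_spec,
            holiday=config.holiday,
        )
        subgroups[key] = {
            "levels": {
                lvl: {"n_cases": r.n_cases, "or_per_10": r.or_per_10}
                for lvl, r in levels.items()
            },
            "wald": pairwise_wald(levels).to_dict(orient="records"),
        }

    series = attribution_series(cases, panel, lag_spec)
    rng = np.random.default_rng([int(config.seed), 2])  # mc substream
    burden = mc_confidence(
        series, main_fit, scenarios=_scenarios(config),
        n_sim=config.n_sim, seed=rng,
    )

    sensitivity = []
    for variant in config.sensitivity_grid():
        v_lag = LagSpec.parse(variant["lag"])
        v_temp = temp_spec_from(variant["temp_lags"], variant["temp_df"])
        _, _, v_fit, _ = _fit_main(cases, panel, v_lag, v_temp, config.holiday)
        sensitivity.append({**variant, **or_per_increment(v_fit)})

    descriptive = summarize(cases, panel)

    bundle = {
        "provenance": {
            "package": "ccburden",
            "version": __version__,
            "config_hash": config.hash(),
            "seed": config.seed,
        },
        "counts": {
            "n_cases": int(len(cases)),
            "n_panel_rows": int(len(panel)),
            "n_sets": int(dm.n_sets),
            **dropped,
            "fit_iterations": main_fit.n_iter,
        },
        "fit": {
            "or_per_10": main_or,
            "loglik": main_fit.loglik,
            "converged": bool(main_fit.converged),
            "beta": dict(zip(main_fit.colnames, main_fit.beta.tolist())),
        },
        "subgroups": subgroups,
        "burden": [asdict(b) for b in burden],
        "sensitivity": sensitivity,
    }

    (out / "results.json").write_text(json.dumps(bundle, indent=2, default=float))
    descriptive.to_csv(out / "descriptives.csv", index=False)
    if sensitivity:
        pd.DataFrame(sensitivity).to_csv(out / "sensitivity.csv", index=False)
    return bundle
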