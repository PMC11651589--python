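"""Run configuration: YAML round-trip and the sensitivity-variant grid."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .basis import CrossBasisSpec, SplineSpec
from .design import LagSpec

__all__ = ["RunConfig", "load_config", "temp_spec_from"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs, serialisable to YAML.

    ``temp_lags``/``temp_df`` parameterise the cross-basis adjustment
    (main model: lags 0–2, 4 df).  ``sensitivity`` optionally enumerates a
    grid of exposure-lag and temperature variants, each refit on the same
    data.
    """

    cases_path: str | None = None
    panel_path: str | None = None
    out_dir: str = "results"
    lag: str = "ma:0-2"
    temp_lags: int = 2
    temp_df: int = 4
    holiday: bool = True
    subgroups: list = field(default_factory=lambda: [
        "sex", "age_group", "urban", "grdp_high", "season",
        ["season", "age_group"],
    ])
    scenarios: list = field(default_factory=lambda: [
        {"kind": "whole_range", "name": "whole_range"},
        {"kind": "above_threshold", "threshold": 15.0, "name": "who_15"},
        {"kind": "above_threshold", "threshold": 35.0, "name": "naaqs_kas_35"},
    ])
    n_sim: int = 1000
    seed: int = 1
    sensitivity: dict | None = None
    synth: dict | None = None  # optional SynthConfig overrides for `run --synth`

    def lag_spec(self) -> LagSpec:
        return LagSpec.parse(self.lag)

    def temp_spec(self) -> CrossBasisSpec:
        return temp_spec_from(self.temp_lags, self.temp_df)

    def sensitivity_grid(self) -> list[dict]:
        """Cartesian grid of model variants (each a valid spec)."""
        if not self.sensitivity:
            return []
        exposure = self.sensitivity.get("exposure_lags", [self.lag])
        t_lags = self.sensitivity.get("temp_lags", [self.temp_lags])
        t_df = self.sensitivity.get("temp_df", [self.temp_df])
        grid = []
        for e in exposure:
            LagSpec.parse(e)  # validate early
            for tl in t_lags:
                for df in t_df:
                    temp_spec_from(int(tl), int(df))
                    grid.append({"lag": e, "temp_lags": int(tl), "temp_df": int(df)})
        return grid

    def hash(self) -> str:
        """Fingerprint of the analysis settings (output location excluded)."""
        payload = asdict(self)
        payload.pop("out_dir")
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def temp_spec_from(temp_lags: int, temp_df: int) -> CrossBasisSpec:
    """Cross-basis spec for a given lag length and exposure-response df.

    The lag-dimension spline keeps one interior knot at lag 1 for the
    2-day window and adds a mid-window knot for longer windows, always
    with an intercept.
    """
    if temp_lags < 1:
        raise ValueError("temperature adjustment needs at least lag 1")
    knots: tuple[float, ...]
    if temp_lags <= 3:
        knots = (1.0,)
    else:
        knots = (1.0, float(temp_lags) / 2.0)
    return CrossBasisSpec(
        var=SplineSpec(df=temp_df),
        lag_range=(0, temp_lags),
        lag_knots=knots,
    )


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**data)
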