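"""Run configuration and result serialization.

Configurations are plain-text YAML with one section per concern
(``model``, ``parameters``, ``inputs``, ``schedule``, ``solver``, ``run``).
Unknown keys are rejected rather than ignored, so typos cannot silently
fall back to defaults.  Result tables are written as CSV with 12
significant digits and a manifest that echoes the configuration, package
version and seed so a run can be reproduced exactly.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import VARIANTS, LightSchedule
from .params import (
    PARAM_NAMES,
    RATE_SCALE_PARAMS,
    IndependentInputs,
    ParameterSet,
)
from .fixtures import reference_fixture

__all__ = ["RunConfig", "load_config", "write_results", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


_INPUT_KEYS = ("acetoacetylCoA", "G3P", "pyruvate", "acCoA_H", "pyruvate_H", "theta")


@dataclass(frozen=True)
class RunConfig:
    """A fully validated run configuration with defaults filled in."""

    variant: str = "E"
    schedule: LightSchedule = field(default_factory=LightSchedule)
    n_days: int = 10
    rtol: float = 1e-8
    atol: float = 1e-12
    sweep_grid: tuple[float, ...] = tuple(float(x) for x in np.arange(0.5, 24.0, 0.5))
    out_dir: str = "results"
    seed: int = 0
    time_unit_scale: float = 1.0
    param_overrides: dict[str, float] = field(default_factory=dict)
    input_overrides: dict[str, float] = field(default_factory=dict)

    def build(self) -> tuple[ParameterSet, IndependentInputs]:
        """Materialize the parameter set and inputs for this run."""
        bundle = reference_fixture()
        params = bundle.params
        if self.param_overrides:
            params = params.replace(**self.param_overrides)
        inputs = bundle.inputs
        if self.input_overrides:
            inputs = inputs.replace(**self.input_overrides)
        if self.time_unit_scale != 1.0:
            scale = {
                k: getattr(params, k) * self.time_unit_scale
                for k in RATE_SCALE_PARAMS
            }
            params = params.replace(**scale)
        return params, inputs


def _reject_unknown(section: str, given: dict, allowed: tuple[str, ...]) -> None:
    unknown = set(given) - set(allowed)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section {section!r}: {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}"
        )


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration (``None``/empty: defaults)."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    _reject_unknown(
        "<root>", raw, ("model", "parameters", "inputs", "schedule", "solver", "run")
    )

    model = raw.get("model") or {}
    _reject_unknown("model", model, ("variant", "time_unit_scale"))
    variant = str(model.get("variant", "E")).upper()
    if variant not in VARIANTS:
        raise ConfigError(
            f"unknown model variant {variant!r}; valid: {', '.join(VARIANTS)}"
        )
    time_unit_scale = float(model.get("time_unit_scale", 1.0))
    if time_unit_scale <= 0:
        raise ConfigError("time_unit_scale must be positive")

    sched_raw = raw.get("schedule") or {}
    _reject_unknown("schedule", sched_raw, ("period", "dawn", "dusk", "T"))
    period = float(sched_raw.get("period", 24.0))
    dusk = float(sched_raw.get("dusk", 12.0))
    if not 0.0 <= dusk <= period:
        raise ConfigError(f"dusk must lie in [0, period]; got dusk={dusk}")
    try:
        schedule = LightSchedule(
            period=period,
            dawn=float(sched_raw.get("dawn", 0.0)),
            dusk=dusk,
            T=float(sched_raw.get("T", 1.0)),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    solver = raw.get("solver") or {}
    _reject_unknown("solver", solver, ("rtol", "atol"))

    run = raw.get("run") or {}
    _reject_unknown("run", run, ("n_days", "sweep_grid", "out_dir", "seed"))
    n_days = int(run.get("n_days", 10))
    if n_days < 1:
        raise ConfigError("n_days must be >= 1")
    grid = run.get("sweep_grid")
    sweep_grid = (
        tuple(float(g) for g in grid)
        if grid is not None
        else tuple(float(x) for x in np.arange(0.5, 24.0, 0.5))
    )
    for g in sweep_grid:
        if not 0.0 < g < period:
            raise ConfigError(f"sweep_grid values must lie in (0, period); got {g}")

    params_raw = raw.get("parameters") or {}
    _reject_unknown("parameters", params_raw, PARAM_NAMES)
    inputs_raw = raw.get("inputs") or {}
    _reject_unknown("inputs", inputs_raw, _INPUT_KEYS)

    return RunConfig(
        variant=variant,
        schedule=schedule,
        n_days=n_days,
        rtol=float(solver.get("rtol", 1e-8)),
        atol=float(solver.get("atol", 1e-12)),
        sweep_grid=sweep_grid,
        out_dir=str(run.get("out_dir", "results")),
        seed=int(run.get("seed", 0)),
        time_unit_scale=time_unit_scale,
        param_overrides={k: float(v) for k, v in params_raw.items()},
        input_overrides={k: float(v) for k, v in inputs_raw.items()},
    )


def dump_config(config: RunConfig) -> str:
    """Serialize a RunConfig to YAML (round-trips through load_config)."""
    doc = {
        "model": {
            "variant": config.variant,
            "time_unit_scale": float(config.time_unit_scale),
        },
        "schedule": {
            "period": float(config.schedule.period),
            "dawn": float(config.schedule.dawn),
            "dusk": float(config.schedule.dusk),
            "T": float(config.schedule.T),
        },
        "solver": {"rtol": float(config.rtol), "atol": float(config.atol)},
        "run": {
            "n_days": int(config.n_days),
            "sweep_grid": [float(g) for g in config.sweep_grid],
            "out_dir": str(config.out_dir),
            "seed": int(config.seed),
        },
        "parameters": {k: float(v) for k, v in config.param_overrides.items()},
        "inputs": {k: float(v) for k, v in config.input_overrides.items()},
    }
    return yaml.safe_dump(doc, sort_keys=True)


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: RunConfig | None = None,
    extra_manifest: dict | None = None,
) -> Path:
    """Write result tables as CSV plus a manifest; returns the manifest path.

    Tables are serialized with 12 significant digits and stable column
    order, so identical runs produce byte-identical CSVs.  On any I/O
    failure all partially written files of this call are removed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    t0 = time.time()
    try:
        for name, df in tables.items():
            path = out / f"{name}.csv"
            df.to_csv(path, float_format="%.12g")
            written.append(path)
        manifest = {
            "package": "terpclock",
            "version": __version__,
            "tables": [p.name for p in written],
            "wall_time_s": round(time.time() - t0, 3),
        }
        if config is not None:
            manifest["config"] = yaml.safe_load(dump_config(config))
            manifest["seed"] = config.seed
        if extra_manifest:
            manifest.update(extra_manifest)
        mpath = out / "manifest.yaml"
        mpath.write_text(yaml.safe_dump(manifest, sort_keys=True))
        written.append(mpath)
        return mpath
    except OSError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
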