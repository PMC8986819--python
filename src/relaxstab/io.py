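"""Run configuration, validation, and tabular/JSON result writers.

A run is described by a :class:`RunConfig`: the stage name, a
stage-specific spec block, a master seed, and an output directory.  Config
files are JSON (YAML also accepted when PyYAML is available); every field
is validated with units fixed package-wide (times ms, b ms/mm^2, ADC
mm^2/ms), defaults are filled in, and the effective config is echoed into
the output provenance so a run is reproducible from its config file alone.

Writers emit CSV tables with full double precision (repr round-trip) and a
manifest of files written; rerunning with the same config overwrites in
place and produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .experiment import ExperimentEmulation, cpmg_te_grid, ir_ti_schedule
from .montecarlo import FitConfig
from .sweeps import (
    SweepResult,
    SweepSpec,
    default_b_grid,
    default_te_grid,
    default_ti_grid,
)

__all__ = ["RunConfig", "load_config", "write_results", "get_logger"]

log = logging.getLogger("relaxstab")


def get_logger(level: str = "INFO") -> logging.Logger:
    """Package logger with a plain stderr handler (idempotent)."""
    if not log.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(h)
    log.setLevel(level.upper())
    return log


class ModelSpec(BaseModel):
    """Two-component base model; null entries are filled by the sweep."""

    c: tuple[float, float]
    T2: tuple[float | None, float | None]
    T1: tuple[float | None, float | None] | None = None
    ADC: tuple[float | None, float | None] | None = None

    @model_validator(mode="after")
    def _positive(self) -> "ModelSpec":
        for name in ("c", "T2", "T1"):
            vals = getattr(self, name)
            if vals is None:
                continue
            for v in vals:
                if v is not None and v <= 0:
                    raise ValueError(f"{name} entries must be > 0, got {v}")
        if self.ADC is not None:
            for v in self.ADC:
                if v is not None and v < 0:
                    raise ValueError(f"ADC entries must be >= 0, got {v}")
        return self


class SweepStage(BaseModel):
    """Config block shared by the sweep stages."""

    base: ModelSpec | None = None
    swept: dict[str, list[float]] | None = None
    TE: list[float] | None = None
    TI: list[float] | None = None
    b: list[float] | None = None
    snr: float = Field(default=1e4, gt=0)
    mode: Literal["analytic", "monte-carlo", "both"] = "analytic"
    n_realizations: int = Field(default=1000, ge=2)
    init_fraction: float = Field(default=0.10, gt=0, lt=1)


class CondStage(BaseModel):
    preset: Literal["left", "right"] = "left"
    base: ModelSpec | None = None
    T1_1: float = Field(default=1000.0, gt=0)
    ADC_1: float = Field(default=1.5, ge=0)
    T1_2_values: list[float] | None = None
    ADC_2_values: list[float] | None = None


class EmulateStage(BaseModel):
    snr_1d: float = Field(default=9000.0, gt=0)
    snr_2d: float = Field(default=2000.0, gt=0)
    n_repeats: int = Field(default=100, ge=2)
    TI: list[float] | None = None  # explicit 24-step schedule override
    init_fraction: float = Field(default=0.10, gt=0, lt=1)
    amplitude_constraint: bool = True


class RunConfig(BaseModel):
    """Top-level run description: stage + spec + seed + output location."""

    stage: Literal[
        "demo-fig1", "sweep1d", "sweep2d", "sweep3d", "cond", "emulate", "analyze"
    ]
    spec: dict[str, Any] = Field(default_factory=dict)
    seed: int = 0
    out: str = "results"
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _validate_stage_spec(self) -> "RunConfig":
        self.stage_spec()  # raises with field context on violation
        return self

    def stage_spec(self) -> BaseModel | None:
        if self.stage.startswith("sweep"):
            parsed = SweepStage(**self.spec)
            dims = _stage_dims(self.stage)
            if parsed.TI is not None and "T1" not in dims:
                raise ValueError("TI axis given but stage model has no T1")
            return parsed
        if self.stage == "cond":
            return CondStage(**self.spec)
        if self.stage in ("emulate", "analyze"):
            return EmulateStage(**self.spec)
        return None  # demo-fig1 takes no spec

    # ---- construction of runtime objects -------------------------------

    def sweep_spec(self) -> SweepSpec:
        stage = self.stage
        s = self.stage_spec()
        assert isinstance(s, SweepStage)
        defaults = _SWEEP_DEFAULTS[stage]
        base = (
            s.base.model_dump(exclude_none=False)
            if s.base is not None
            else defaults["base"]
        )
        base = {k: tuple(v) for k, v in base.items() if v is not None}
        swept = s.swept if s.swept else defaults["swept"]
        TE = np.asarray(s.TE, float) if s.TE else default_te_grid()
        if stage == "sweep1d":
            TI = None
            b = None
        else:
            TI = np.asarray(s.TI, float) if s.TI else default_ti_grid()
            b = None
            if stage == "sweep3d":
                b = np.asarray(s.b, float) if s.b else default_b_grid()
        return SweepSpec(
            base=base,
            swept=swept,
            TE=TE,
            TI=TI,
            b=b,
            snr=s.snr,
            mode=s.mode,
            n_realizations=s.n_realizations,
            fit=FitConfig(init_fraction=s.init_fraction, seed=self.seed),
        )

    def emulation(self) -> ExperimentEmulation:
        s = self.stage_spec()
        assert isinstance(s, EmulateStage)
        TI = np.asarray(s.TI, float) if s.TI else ir_ti_schedule()
        return ExperimentEmulation(
            TE=cpmg_te_grid(),
            TI=TI,
            snr_1d=s.snr_1d,
            snr_2d=s.snr_2d,
            n_repeats=s.n_repeats,
            seed=self.seed,
        )


def _stage_dims(stage: str) -> tuple[str, ...]:
    return {
        "sweep1d": ("T2",),
        "sweep2d": ("T1", "T2"),
        "sweep3d": ("T1", "T2", "ADC"),
    }[stage]


_SWEEP_DEFAULTS: dict[str, dict] = {
    "sweep1d": {
        "base": {"c": (0.3, 0.7), "T2": (60.0, None)},
        "swept": {"T2_2": [61.0, 65.0, 70.0, 80.0, 100.0, 150.0]},
    },
    "sweep2d": {
        "base": {"c": (0.3, 0.7), "T2": (60.0, 45.0), "T1": (1000.0, None)},
        "swept": {"T1_2": list(np.arange(800.0, 1200.0 + 1e-9, 25.0))},
    },
    "sweep3d": {
        "base": {
            "c": (0.7, 0.3),
            "T2": (45.0, 60.0),
            "T1": (1000.0, None),
            "ADC": (1.5, None),
        },
        "swept": {
            "T1_2": list(np.arange(800.0, 1200.0 + 1e-9, 50.0)),
            "ADC_2": list(np.arange(0.5, 2.5 + 1e-9, 0.25)),
        },
    },
}


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a JSON (or YAML) run configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    return RunConfig(**doc)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_results(
    result: SweepResult | pd.DataFrame | dict,
    outdir: str | Path,
    name: str = "result",
    config: RunConfig | None = None,
) -> list[Path]:
    """Write a result to ``outdir``; returns the manifest of files written.

    Emits ``<name>.csv`` for tabular content, ``<name>.json`` for summary
    dicts, and a ``<name>.provenance.json`` block (config hash, seed,
    package version, and any provenance carried by the result).  Existing
    files are overwritten; identical inputs produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    provenance: dict[str, Any] = {"version": __version__}
    if config is not None:
        provenance["config"] = config.model_dump()
        provenance["config_hash"] = _config_hash(config)
        provenance["seed"] = config.seed

    if isinstance(result, SweepResult):
        table, extra = result.rows, result.provenance
    elif isinstance(result, pd.DataFrame):
        table, extra = result, {}
    else:
        table, extra = None, dict(result)

    if table is not None:
        csv_path = outdir / f"{name}.csv"
        # repr keeps full double precision so regression diffs are exact
        table.to_csv(csv_path, index=False, float_format=lambda x: repr(float(x)))
        written.append(csv_path)
    else:
        json_path = outdir / f"{name}.json"
        json_path.write_text(json.dumps(extra, indent=2, default=_jsonable))
        written.append(json_path)
        extra = {}

    prov_path = outdir / f"{name}.provenance.json"
    provenance.update({"result_provenance": extra} if extra else {})
    prov_path.write_text(json.dumps(provenance, indent=2, default=_jsonable))
    written.append(prov_path)

    manifest = outdir / f"{name}.manifest.json"
    manifest.write_text(
        json.dumps([p.name for p in written + [manifest]], indent=2)
    )
    written.append(manifest)
    log.info("wrote %d files to %s", len(written), outdir)
    return written


def _jsonable(obj: Any):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
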