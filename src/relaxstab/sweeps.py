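"""Parameter-sweep experiments: SD and condition-number curves/surfaces.

These stages reproduce the canonical stability experiments for the
biexponential model: sweep one underlying parameter (or two, in 3D),
recompute the linearized covariance and/or run a Monte-Carlo experiment at
each value, and tabulate per-parameter SDs and the Jacobian condition
number.  Default grids are the conventional simulation design:

* TE from 8 ms to 512 ms in 8 ms steps (n_TE = 64),
* TI from 50 ms to 4850 ms in 200 ms steps (n_TI = 25),
* b from 0 to 2 ms/mm^2 in 0.25 ms/mm^2 steps (n_b = 9),

so the 2D grid has 1600 measurement points and the 3D grid 14,400.
Each result row carries full provenance (spec echo + seed), making every
table reproducible from its provenance block alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .models import (
    AcquisitionGrid,
    Component,
    MultiComponentModel,
    eval_jacobian,
)
from .montecarlo import FitConfig, run_mc
from .stability import NoiseSpec, condition_number, nonlinear_covariance

__all__ = [
    "default_te_grid",
    "default_ti_grid",
    "default_b_grid",
    "SweepSpec",
    "SweepResult",
    "sweep_1d_coalescence",
    "sweep_2d_T1separation",
    "sweep_condition_numbers",
    "sweep_3d",
    "FIG6_LEFT",
    "FIG6_RIGHT",
]


def default_te_grid() -> np.ndarray:
    """64 evenly spaced echo times, 8..512 ms in 8 ms steps."""
    return np.arange(8.0, 512.0 + 1e-9, 8.0)


def default_ti_grid() -> np.ndarray:
    """25 inversion times, 50..4850 ms in 200 ms steps."""
    return np.arange(50.0, 4850.0 + 1e-9, 200.0)


def default_b_grid() -> np.ndarray:
    """9 diffusion weightings, 0..2 ms/mm^2 in 0.25 steps."""
    return np.arange(0.0, 2.0 + 1e-9, 0.25)


# Condition-number comparison presets: (c1, c2, T2_1, T2_2) as conventionally
# printed; the model container canonicalizes to ascending T2.
FIG6_LEFT = {"c": (0.3, 0.7), "T2": (60.0, 45.0)}
FIG6_RIGHT = {"c": (0.8, 0.2), "T2": (90.0, 160.0)}


@dataclass(frozen=True)
class SweepSpec:
    """One sweep: a base model, one or two swept attributes, grid, noise.

    ``swept`` maps an attribute of the *second* canonical component
    ("T2_2", "T1_2", "ADC_2") to the list of values it takes.  ``mode``
    selects analytic covariance rows, Monte-Carlo rows, or both.
    """

    base: dict
    swept: dict[str, Sequence[float]]
    TE: np.ndarray = field(default_factory=default_te_grid)
    TI: np.ndarray | None = None
    b: np.ndarray | None = None
    snr: float = 1e4
    mode: str = "analytic"  # analytic | monte-carlo | both
    n_realizations: int = 1000
    fit: FitConfig = field(default_factory=FitConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("analytic", "monte-carlo", "both"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.swept or len(self.swept) > 2:
            raise ValueError("sweep needs one or two swept attributes")
        for name, vals in self.swept.items():
            if name not in ("T2_2", "T1_2", "ADC_2"):
                raise ValueError(f"unsupported swept attribute {name!r}")
            if len(vals) == 0:
                raise ValueError(f"swept values for {name} are empty")

    def grid(self) -> AcquisitionGrid:
        return AcquisitionGrid(TE=self.TE, TI=self.TI, b=self.b)

    def model_at(self, **overrides: float) -> MultiComponentModel:
        """Instantiate the two-component model with swept values plugged in."""
        base = dict(self.base)
        c = base["c"]
        T2 = list(base["T2"])
        T1 = list(base.get("T1", (None, None)))
        ADC = list(base.get("ADC", (None, None)))
        for name, val in overrides.items():
            attr, idx = name.rsplit("_", 1)
            i = int(idx) - 1
            {"T2": T2, "T1": T1, "ADC": ADC}[attr][i] = val
        comps = [
            Component(amplitude=c[i], T2=T2[i], T1=T1[i], ADC=ADC[i])
            for i in range(2)
        ]
        return MultiComponentModel(comps)

    def provenance(self) -> dict:
        return {
            "base": {k: list(v) for k, v in self.base.items()},
            "swept": {k: [float(x) for x in v] for k, v in self.swept.items()},
            "TE": self.TE.tolist(),
            "TI": self.TI.tolist() if self.TI is not None else None,
            "b": self.b.tolist() if self.b is not None else None,
            "snr": self.snr,
            "mode": self.mode,
            "n_realizations": self.n_realizations,
            "seed": self.fit.seed,
            "init_fraction": self.fit.init_fraction,
        }


@dataclass(frozen=True, eq=False)
class SweepResult:
    """Tidy table of sweep rows plus the provenance needed to regenerate it."""

    rows: pd.DataFrame
    provenance: dict


def _analytic_row(model: MultiComponentModel, grid: AcquisitionGrid, snr: float) -> dict:
    report = nonlinear_covariance(model, grid, NoiseSpec(snr=snr))
    row = {f"sd_{k}": v for k, v in report.sd_by_label().items()}
    row["cond"] = report.condition_number
    row["singular"] = report.singular
    return row


def _mc_row(
    model: MultiComponentModel,
    grid: AcquisitionGrid,
    snr: float,
    n_realizations: int,
    fit: FitConfig,
) -> dict:
    summary = run_mc(model, grid, NoiseSpec(snr=snr), n_realizations, fit)
    row = {f"mc_sd_{k}": v for k, v in summary.sd_by_label().items()}
    row.update({f"mc_mean_{k}": v for k, v in summary.mean_by_label().items()})
    row["mc_failures"] = summary.failure_count
    return row


def _run_sweep(spec: SweepSpec) -> SweepResult:
    """Shared driver: cartesian product over the swept axes."""
    grid = spec.grid()
    names = list(spec.swept)
    axes = [np.asarray(spec.swept[n], dtype=float) for n in names]
    mesh = (
        [(v,) for v in axes[0]]
        if len(axes) == 1
        else [(a, b) for a in axes[0] for b in axes[1]]
    )
    rows = []
    for k, values in enumerate(mesh):
        row: dict = dict(zip(names, (float(v) for v in values)))
        model = spec.model_at(**row)
        if spec.mode in ("analytic", "both"):
            row.update(_analytic_row(model, grid, spec.snr))
        if spec.mode in ("monte-carlo", "both"):
            fit = FitConfig(
                init_fraction=spec.fit.init_fraction,
                max_iterations=spec.fit.max_iterations,
                xtol=spec.fit.xtol,
                ftol=spec.fit.ftol,
                gtol=spec.fit.gtol,
                seed=spec.fit.seed + k,  # independent stream per swept value
                amplitude_constraint=spec.fit.amplitude_constraint,
            )
            row.update(
                _mc_row(model, grid, spec.snr, spec.n_realizations, fit)
            )
        rows.append(row)
    return SweepResult(rows=pd.DataFrame(rows), provenance=spec.provenance())


def sweep_1d_coalescence(spec: SweepSpec | None = None) -> SweepResult:
    """SDs and cond(B) for the 1D biexponential model as T2_2 varies.

    Default: (c1, c2, T2_1) = (0.3, 0.7, 60 ms), T2_2 swept over
    61..150 ms, SNR 1e4 in Monte-Carlo mode.  A swept value equal to T2_1
    produces a singular-flagged row (component coalescence), not an error.
    """
    if spec is None:
        spec = SweepSpec(
            base={"c": (0.3, 0.7), "T2": (60.0, None)},
            swept={"T2_2": [61.0, 65.0, 70.0, 80.0, 100.0, 150.0]},
        )
    if "T2_2" not in spec.swept:
        raise ValueError("1D coalescence sweep must sweep T2_2")
    return _run_sweep(spec)


def sweep_2d_T1separation(spec: SweepSpec | None = None, mc: bool = False) -> SweepResult:
    """2D T1-T2 sweep over T1_2 with T1_1 fixed at 1000 ms.

    Analytic default base: (c1, c2, T2_1, T2_2) = (0.3, 0.7, 60, 45) ms;
    Monte-Carlo default base swaps the T2 roles, (0.3, 0.7, 45, 60) ms at
    SNR 400 — both conventional presentations of the same physical family
    (canonical relabeling maps between them).  T1_2 defaults to
    800..1200 ms.
    """
    if spec is None:
        if mc:
            spec = SweepSpec(
                base={"c": (0.3, 0.7), "T2": (45.0, 60.0), "T1": (1000.0, None)},
                swept={"T1_2": list(np.arange(800.0, 1200.0 + 1e-9, 50.0))},
                TI=default_ti_grid(),
                snr=400.0,
                mode="monte-carlo",
            )
        else:
            spec = SweepSpec(
                base={"c": (0.3, 0.7), "T2": (60.0, 45.0), "T1": (1000.0, None)},
                swept={"T1_2": list(np.arange(800.0, 1200.0 + 1e-9, 25.0))},
                TI=default_ti_grid(),
            )
    if "T1_2" not in spec.swept:
        raise ValueError("2D separation sweep must sweep T1_2")
    if spec.TI is None:
        raise ValueError("2D sweep needs a TI axis")
    return _run_sweep(spec)


def sweep_3d(spec: SweepSpec | None = None) -> SweepResult:
    """3D T1-T2-ADC sweep over the (T1_2, ADC_2) surface.

    Default base: (c1, c2, T2_1, T2_2, T1_1, ADC_1) =
    (0.7, 0.3, 45 ms, 60 ms, 1000 ms, 1.5 mm^2/ms); T1_2 over
    800..1200 ms and ADC_2 over 0.5..2.5 mm^2/ms.
    """
    if spec is None:
        spec = SweepSpec(
            base={
                "c": (0.7, 0.3),
                "T2": (45.0, 60.0),
                "T1": (1000.0, None),
                "ADC": (1.5, None),
            },
            swept={
                "T1_2": list(np.arange(800.0, 1200.0 + 1e-9, 50.0)),
                "ADC_2": list(np.arange(0.5, 2.5 + 1e-9, 0.25)),
            },
            TI=default_ti_grid(),
            b=default_b_grid(),
        )
    if set(spec.swept) != {"T1_2", "ADC_2"}:
        raise ValueError("3D sweep must sweep T1_2 and ADC_2")
    return _run_sweep(spec)


def sweep_condition_numbers(
    base: dict | None = None,
    T1_2_values: Sequence[float] | None = None,
    ADC_2_values: Sequence[float] | None = None,
    T1_1: float = 1000.0,
    ADC_1: float = 1.5,
    TE: np.ndarray | None = None,
    TI: np.ndarray | None = None,
    b: np.ndarray | None = None,
    time_scale: float = 1e-3,
) -> SweepResult:
    """cond(B) for 1D, 2D and optionally 3D models on matched settings.

    The 1D condition number is constant along the indirect axes (the 1D
    model has no T1 or ADC) and is repeated across rows for comparison.
    ``base`` supplies (c, T2) in ms as in the presets
    ``FIG6_LEFT``/``FIG6_RIGHT``.

    cond(B) is unit-dependent because the parameter vector mixes
    dimensionless amplitudes with time constants.  For the comparison
    across dimensionalities to be meaningful, the Jacobian is evaluated
    with all times expressed in seconds (``time_scale=1e-3`` from the
    package's ms convention), which puts every parameter — amplitudes
    ~O(1), relaxation times 0.04..2 s, ADC in mm^2/ms ~O(1) with
    b.ADC dimensionless — on a comparable scale.  In ms the O(10^3)
    scale gap between amplitudes and T1 values dominates the singular
    spectrum and masks the conditioning structure.  Set ``time_scale=1``
    to evaluate in ms instead.
    """
    base = dict(FIG6_LEFT) if base is None else dict(base)
    if T1_2_values is None:
        T1_2_values = np.arange(500.0, 2000.0 + 1e-9, 100.0)
    TE = default_te_grid() if TE is None else np.asarray(TE, float)
    TI = default_ti_grid() if TI is None else np.asarray(TI, float)
    c, T2 = base["c"], base["T2"]
    ts = float(time_scale)

    grid_1d = AcquisitionGrid(TE=TE * ts)
    model_1d = MultiComponentModel(
        [Component(amplitude=c[i], T2=T2[i] * ts) for i in range(2)]
    )
    cond_1d = condition_number(eval_jacobian(model_1d, grid_1d))

    grid_2d = AcquisitionGrid(TE=TE * ts, TI=TI * ts)
    want_3d = ADC_2_values is not None
    if want_3d:
        b = default_b_grid() if b is None else np.asarray(b, float)
        grid_3d = AcquisitionGrid(TE=TE * ts, TI=TI * ts, b=b)

    rows = []
    for T1_2 in np.asarray(T1_2_values, dtype=float):
        model_2d = MultiComponentModel(
            [
                Component(amplitude=c[0], T2=T2[0] * ts, T1=T1_1 * ts),
                Component(amplitude=c[1], T2=T2[1] * ts, T1=T1_2 * ts),
            ]
        )
        cond_2d = condition_number(eval_jacobian(model_2d, grid_2d))
        if not want_3d:
            rows.append(
                {"T1_2": float(T1_2), "cond_1d": cond_1d, "cond_2d": cond_2d}
            )
            continue
        for ADC_2 in np.asarray(ADC_2_values, dtype=float):
            model_3d = MultiComponentModel(
                [
                    Component(amplitude=c[0], T2=T2[0] * ts, T1=T1_1 * ts, ADC=ADC_1),
                    Component(amplitude=c[1], T2=T2[1] * ts, T1=T1_2 * ts, ADC=ADC_2),
                ]
            )
            cond_3d = condition_number(eval_jacobian(model_3d, grid_3d))
            rows.append(
                {
                    "T1_2": float(T1_2),
                    "ADC_2": float(ADC_2),
                    "cond_1d": cond_1d,
                    "cond_2d": cond_2d,
                    "cond_3d": cond_3d,
                }
            )
    provenance = {
        "base": {k: list(v) for k, v in base.items()},
        "T1_1": T1_1,
        "ADC_1": ADC_1,
        "T1_2_values": np.asarray(T1_2_values, float).tolist(),
        "ADC_2_values": (
            np.asarray(ADC_2_values, float).tolist() if want_3d else None
        ),
        "TE": TE.tolist(),
        "TI": TI.tolist(),
        "b": b.tolist() if want_3d else None,
        "time_scale": ts,
    }
    return SweepResult(rows=pd.DataFrame(rows), provenance=provenance)
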