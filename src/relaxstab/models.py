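"""Forward signal models for 1D/2D/3D multicomponent MR relaxometry.

A sample is modelled as a discrete mixture of ``n`` monoexponential
components.  Each component ``i`` carries an amplitude ``c_i``, a transverse
relaxation time ``T2_i`` (ms), and optionally a longitudinal relaxation time
``T1_i`` (ms) and an apparent diffusion coefficient ``ADC_i`` (mm^2/ms).
The noise-free signal on an acquisition grid of echo times ``TE`` (direct
dimension), inversion times ``TI`` and diffusion weightings ``b`` (indirect
dimensions) is

    S = sum_i c_i * exp(-TE/T2_i) * (1 - 2 exp(-TI/T1_i)) * exp(-b*ADC_i)

with the inversion-recovery and diffusion factors present only when the
corresponding grid dimension is present.  The module also provides the
analytic Jacobian of the vectorized signal with respect to the flat
parameter vector, which is the object from which linearized (Cramer-Rao
style) covariance and conditioning statements are derived downstream.

Units are fixed throughout the package: times in ms, ``b`` in ms/mm^2,
``ADC`` in mm^2/ms, amplitudes dimensionless.  Condition numbers of the
Jacobian are unit-dependent, so consistency here matters.

Vectorization convention: the measurement tensor is shaped
``(n_b, n_TI, n_TE)`` (absent dimensions dropped from the front) and is
flattened in C order, i.e. b slowest, then TI, then TE fastest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Dimensionality",
    "Component",
    "MultiComponentModel",
    "AcquisitionGrid",
    "ParamLayout",
    "SignalArray",
    "JacobianMatrix",
    "eval_signal",
    "eval_jacobian",
    "vectorize",
    "devectorize",
    "signal_from_params",
    "jacobian_from_params",
    "model_to_params",
    "params_to_model",
    "model_grid_to_json",
    "model_grid_from_json",
]


class Dimensionality(str, Enum):
    """Which relaxation/diffusion mechanisms the experiment encodes."""

    T2 = "T2"  # 1D: CPMG decay only
    T1T2 = "T1T2"  # 2D: inversion recovery x CPMG
    T1T2ADC = "T1T2ADC"  # 3D: diffusion x inversion recovery x CPMG

    @property
    def has_T1(self) -> bool:
        return self in (Dimensionality.T1T2, Dimensionality.T1T2ADC)

    @property
    def has_ADC(self) -> bool:
        return self is Dimensionality.T1T2ADC

    @property
    def n_attrs(self) -> int:
        """Number of parameters per component (amplitude included)."""
        return 2 + self.has_T1 + self.has_ADC


@dataclass(frozen=True)
class Component:
    """One monoexponential pool: amplitude plus relaxation/diffusion constants.

    ``T1`` and ``ADC`` are optional; within a :class:`MultiComponentModel`
    either every component has them or none does.
    """

    amplitude: float
    T2: float
    T1: float | None = None
    ADC: float | None = None

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError(f"amplitude must be > 0, got {self.amplitude}")
        if not self.T2 > 0:
            raise ValueError(f"T2 must be > 0 ms, got {self.T2}")
        if self.T1 is not None and not self.T1 > 0:
            raise ValueError(f"T1 must be > 0 ms, got {self.T1}")
        if self.ADC is not None and self.ADC < 0:
            raise ValueError(f"ADC must be >= 0 mm^2/ms, got {self.ADC}")

    def _sort_key(self) -> tuple:
        return (
            self.T2,
            self.T1 if self.T1 is not None else 0.0,
            self.ADC if self.ADC is not None else 0.0,
            self.amplitude,
        )


@dataclass(frozen=True)
class MultiComponentModel:
    """Ordered mixture of components; order is canonical (ascending T2).

    Ties on T2 break by ascending T1, then ADC, then amplitude, matching
    the relabeling rule applied to fitted parameters.  Construction sorts
    the supplied components, so two permutations of the same pools compare
    equal.
    """

    components: tuple[Component, ...]

    def __init__(self, components: Sequence[Component]):
        comps = tuple(sorted(components, key=Component._sort_key))
        if not comps:
            raise ValueError("model needs at least one component")
        has_T1 = {c.T1 is not None for c in comps}
        has_ADC = {c.ADC is not None for c in comps}
        if len(has_T1) > 1:
            raise ValueError("all components must have T1, or none")
        if len(has_ADC) > 1:
            raise ValueError("all components must have ADC, or none")
        if has_ADC == {True} and has_T1 == {False}:
            raise ValueError("ADC components require T1 as well (3D model)")
        object.__setattr__(self, "components", comps)

    @property
    def n(self) -> int:
        return len(self.components)

    @property
    def dimensionality(self) -> Dimensionality:
        c = self.components[0]
        if c.ADC is not None:
            return Dimensionality.T1T2ADC
        if c.T1 is not None:
            return Dimensionality.T1T2
        return Dimensionality.T2

    # convenience accessors used heavily in sweeps
    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([c.amplitude for c in self.components])

    @property
    def T2s(self) -> np.ndarray:
        return np.array([c.T2 for c in self.components])

    @property
    def T1s(self) -> np.ndarray:
        return np.array([c.T1 for c in self.components], dtype=float)

    @property
    def ADCs(self) -> np.ndarray:
        return np.array([c.ADC for c in self.components], dtype=float)


def _check_axis(name: str, values: np.ndarray, positive: bool) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError(f"{name} must be a nonempty 1D sequence")
    if positive and not np.all(values > 0):
        raise ValueError(f"all {name} values must be > 0")
    if not positive and not np.all(values >= 0):
        raise ValueError(f"all {name} values must be >= 0")
    if not np.all(np.diff(values) > 0):
        raise ValueError(f"{name} values must be strictly increasing")
    return values


@dataclass(frozen=True, eq=False)
class AcquisitionGrid:
    """Sampling schedule: echo times plus optional indirect dimensions.

    ``TE`` (ms) is the direct CPMG readout; ``TI`` (ms) indexes an
    inversion-recovery preparation; ``b`` (ms/mm^2) a diffusion weighting.
    The measurement tensor has shape ``(n_b, n_TI, n_TE)`` with absent
    leading dimensions dropped; total count ``M`` is the product.
    """

    TE: np.ndarray
    TI: np.ndarray | None = None
    b: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "TE", _check_axis("TE", self.TE, positive=True))
        if self.TI is not None:
            object.__setattr__(self, "TI", _check_axis("TI", self.TI, positive=False))
        if self.b is not None:
            object.__setattr__(self, "b", _check_axis("b", self.b, positive=False))
            if self.TI is None:
                raise ValueError("a b axis requires a TI axis in this package")

    @property
    def dimensionality(self) -> Dimensionality:
        if self.b is not None:
            return Dimensionality.T1T2ADC
        if self.TI is not None:
            return Dimensionality.T1T2
        return Dimensionality.T2

    @property
    def shape(self) -> tuple[int, ...]:
        dims: list[int] = []
        if self.b is not None:
            dims.append(self.b.size)
        if self.TI is not None:
            dims.append(self.TI.size)
        dims.append(self.TE.size)
        return tuple(dims)

    @property
    def M(self) -> int:
        return int(np.prod(self.shape))


@dataclass(frozen=True)
class ParamLayout:
    """Mapping between flat parameter index and (component, attribute).

    Layout: all amplitudes first, then all T1s (if present), then all T2s,
    then all ADCs (if present); within each block components in canonical
    order.  For two components this is (c1, c2, T1_1, T1_2, T2_1, T2_2,
    ADC_1, ADC_2), matching the conventional ordering used in 2D
    relaxometry covariance analyses.
    """

    n: int
    dimensionality: Dimensionality

    @property
    def blocks(self) -> tuple[str, ...]:
        names = ["c"]
        if self.dimensionality.has_T1:
            names.append("T1")
        names.append("T2")
        if self.dimensionality.has_ADC:
            names.append("ADC")
        return tuple(names)

    @property
    def N(self) -> int:
        return self.n * len(self.blocks)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(
            f"{blk}_{i + 1}" for blk in self.blocks for i in range(self.n)
        )

    def index(self, attr: str, component: int) -> int:
        """Flat index of ``attr`` (one of c/T1/T2/ADC) for 0-based component."""
        try:
            blk = self.blocks.index(attr)
        except ValueError:
            raise KeyError(f"attribute {attr!r} not present in layout") from None
        return blk * self.n + component


@dataclass(frozen=True, eq=False)
class SignalArray:
    """Noise-free or noisy signal values shaped like the acquisition grid."""

    values: np.ndarray
    grid: AcquisitionGrid

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.shape:
            raise ValueError(
                f"signal shape {values.shape} does not match grid shape {self.grid.shape}"
            )
        object.__setattr__(self, "values", values)


@dataclass(frozen=True, eq=False)
class JacobianMatrix:
    """M x N matrix of partial derivatives of the vectorized signal.

    Rows follow the grid vectorization (b slowest, TE fastest); columns
    follow :class:`ParamLayout`.
    """

    entries: np.ndarray
    grid: AcquisitionGrid
    layout: ParamLayout


def _require_compatible(model_dim: Dimensionality, grid: AcquisitionGrid) -> None:
    if grid.TI is not None and not model_dim.has_T1:
        raise ValueError("grid has a TI axis but the model components lack T1")
    if grid.b is not None and not model_dim.has_ADC:
        raise ValueError("grid has a b axis but the model components lack ADC")
    if model_dim.has_T1 and grid.TI is None:
        raise ValueError("model components have T1 but the grid lacks a TI axis")
    if model_dim.has_ADC and grid.b is None:
        raise ValueError("model components have ADC but the grid lacks a b axis")


# ---------------------------------------------------------------------------
# flat parameter vector <-> model round trip
# ---------------------------------------------------------------------------

def model_to_params(model: MultiComponentModel) -> np.ndarray:
    """Flatten a model into the canonical parameter vector."""
    dim = model.dimensionality
    parts = [model.amplitudes]
    if dim.has_T1:
        parts.append(model.T1s)
    parts.append(model.T2s)
    if dim.has_ADC:
        parts.append(model.ADCs)
    return np.concatenate(parts)


def params_to_model(
    params: np.ndarray, dimensionality: Dimensionality, n: int
) -> MultiComponentModel:
    """Rebuild a model from a flat parameter vector (canonical layout)."""
    blocks = split_params(params, dimensionality, n)
    comps = []
    for i in range(n):
        comps.append(
            Component(
                amplitude=blocks["c"][i],
                T2=blocks["T2"][i],
                T1=blocks["T1"][i] if dimensionality.has_T1 else None,
                ADC=blocks["ADC"][i] if dimensionality.has_ADC else None,
            )
        )
    return MultiComponentModel(comps)


def split_params(
    params: np.ndarray, dimensionality: Dimensionality, n: int
) -> dict[str, np.ndarray]:
    """Split a flat parameter vector into attribute blocks of length ``n``."""
    params = np.asarray(params, dtype=float)
    layout = ParamLayout(n, dimensionality)
    if params.size != layout.N:
        raise ValueError(f"expected {layout.N} parameters, got {params.size}")
    return {
        blk: params[k * n : (k + 1) * n] for k, blk in enumerate(layout.blocks)
    }


# ---------------------------------------------------------------------------
# forward evaluation
# ---------------------------------------------------------------------------

def _kernels(
    blocks: dict[str, np.ndarray], grid: AcquisitionGrid
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    """Per-component separable kernel factors on each grid axis.

    Returns arrays indexed ``[axis_point, component]``: the CPMG decay
    ``exp(-TE/T2_i)``, the inversion-recovery factor ``1 - 2 exp(-TI/T1_i)``
    (None in 1D) and the diffusion attenuation ``exp(-b*ADC_i)`` (None
    below 3D).
    """
    # optimizer trial steps may pass through tiny or negative time constants;
    # let the resulting overflows become inf silently and fail the fit cleanly
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        kTE = np.exp(-grid.TE[:, None] / blocks["T2"][None, :])
        kTI = None
        kb = None
        if grid.TI is not None:
            kTI = 1.0 - 2.0 * np.exp(-grid.TI[:, None] / blocks["T1"][None, :])
        if grid.b is not None:
            kb = np.exp(-grid.b[:, None] * blocks["ADC"][None, :])
    return kTE, kTI, kb


def signal_from_params(
    params: np.ndarray,
    grid: AcquisitionGrid,
    dimensionality: Dimensionality,
    n: int,
) -> np.ndarray:
    """Evaluate the signal tensor for an arbitrary (possibly non-physical)
    flat parameter vector.

    Used by the nonlinear fitter, which must be free to step through
    negative amplitudes or time constants; no positivity checks here
    beyond what the exponentials tolerate numerically.
    """
    _require_compatible(dimensionality, grid)
    blocks = split_params(params, dimensionality, n)
    kTE, kTI, kb = _kernels(blocks, grid)
    c = blocks["c"]
    if kb is not None:
        # (n_b, n_TI, n_TE) <- sum_i c_i * kb[l,i]*kTI[k,i]*kTE[j,i]
        return np.einsum("i,li,ki,ji->lkj", c, kb, kTI, kTE)
    if kTI is not None:
        return np.einsum("i,ki,ji->kj", c, kTI, kTE)
    return kTE @ c


def eval_signal(model: MultiComponentModel, grid: AcquisitionGrid) -> SignalArray:
    """Noise-free signal of ``model`` sampled on ``grid``.

    Raises ``ValueError`` when the grid encodes a mechanism the model
    lacks (or vice versa), naming the missing attribute.
    """
    _require_compatible(model.dimensionality, grid)
    values = signal_from_params(
        model_to_params(model), grid, model.dimensionality, model.n
    )
    return SignalArray(values=values, grid=grid)


# ---------------------------------------------------------------------------
# analytic Jacobian
# ---------------------------------------------------------------------------

def jacobian_from_params(
    params: np.ndarray,
    grid: AcquisitionGrid,
    dimensionality: Dimensionality,
    n: int,
) -> np.ndarray:
    """M x N analytic Jacobian of the vectorized signal at ``params``.

    Derivatives of the separable kernel product, per component i:

        dS/dc_i   = kTE_i * kTI_i * kb_i
        dS/dT1_i  = c_i * kTE_i * kb_i * (-2 TI / T1_i^2) exp(-TI/T1_i)
        dS/dT2_i  = c_i * kTI_i * kb_i * (TE / T2_i^2) exp(-TE/T2_i)
        dS/dADC_i = c_i * kTE_i * kTI_i * (-b) exp(-b ADC_i)
    """
    _require_compatible(dimensionality, grid)
    blocks = split_params(params, dimensionality, n)
    kTE, kTI, kb = _kernels(blocks, grid)
    c = blocks["c"]
    T2 = blocks["T2"]

    # derivative factors along each axis, indexed [axis_point, component]
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        dTE = kTE * (grid.TE[:, None] / T2[None, :] ** 2)

    def assemble(fTE: np.ndarray, fTI: np.ndarray | None, fb: np.ndarray | None,
                 scale: np.ndarray) -> np.ndarray:
        """Column block: vectorized product of per-axis factors, one column
        per component, scaled per component."""
        if kb is not None:
            out = np.einsum("i,li,ki,ji->lkji", scale, fb, fTI, fTE)
        elif kTI is not None:
            out = np.einsum("i,ki,ji->kji", scale, fTI, fTE)
        else:
            out = scale[None, :] * fTE
        return out.reshape(-1, n)

    one = np.ones(n)
    cols = [assemble(kTE, kTI, kb, one)]  # d/dc
    if dimensionality.has_T1:
        T1 = blocks["T1"]
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            dTI = -2.0 * (grid.TI[:, None] / T1[None, :] ** 2) * np.exp(
                -grid.TI[:, None] / T1[None, :]
            )
        cols.append(assemble(kTE, dTI, kb, c))
    cols.append(assemble(dTE, kTI, kb, c))  # d/dT2
    if dimensionality.has_ADC:
        db = -grid.b[:, None] * kb
        cols.append(assemble(kTE, kTI, db, c))
    return np.concatenate(cols, axis=1)


def eval_jacobian(model: MultiComponentModel, grid: AcquisitionGrid) -> JacobianMatrix:
    """Analytic Jacobian of the signal with respect to the parameter vector,
    evaluated at the model's own (true) parameters."""
    layout = ParamLayout(model.n, model.dimensionality)
    entries = jacobian_from_params(
        model_to_params(model), grid, model.dimensionality, model.n
    )
    return JacobianMatrix(entries=entries, grid=grid, layout=layout)


# ---------------------------------------------------------------------------
# vectorization
# ---------------------------------------------------------------------------

def vectorize(signal: SignalArray | np.ndarray) -> np.ndarray:
    """Flatten a measurement tensor: b slowest, then TI, then TE fastest."""
    values = signal.values if isinstance(signal, SignalArray) else np.asarray(signal)
    return values.reshape(-1)


def devectorize(flat: np.ndarray, grid: AcquisitionGrid) -> np.ndarray:
    """Inverse of :func:`vectorize` for a given grid."""
    flat = np.asarray(flat)
    if flat.size != grid.M:
        raise ValueError(f"expected {grid.M} values, got {flat.size}")
    return flat.reshape(grid.shape)


# ---------------------------------------------------------------------------
# JSON serialization (units fixed: ms, ms/mm^2, mm^2/ms)
# ---------------------------------------------------------------------------

_UNITS = {"time": "ms", "b": "ms/mm^2", "ADC": "mm^2/ms"}


def model_grid_to_json(
    model: MultiComponentModel, grid: AcquisitionGrid
) -> dict:
    """Serialize a (model, grid) pair to a plain JSON-compatible dict."""
    comps = []
    for c in model.components:
        entry: dict[str, float] = {"c": c.amplitude, "T2": c.T2}
        if c.T1 is not None:
            entry["T1"] = c.T1
        if c.ADC is not None:
            entry["ADC"] = c.ADC
        comps.append(entry)
    doc: dict = {"units": _UNITS, "components": comps, "TE": grid.TE.tolist()}
    if grid.TI is not None:
        doc["TI"] = grid.TI.tolist()
    if grid.b is not None:
        doc["b"] = grid.b.tolist()
    return doc


def model_grid_from_json(
    doc: dict | str | Path,
) -> tuple[MultiComponentModel, AcquisitionGrid]:
    """Inverse of :func:`model_grid_to_json`; accepts a dict, JSON string,
    or path to a JSON file."""
    if isinstance(doc, (str, Path)):
        p = Path(doc)
        text = p.read_text() if p.exists() else str(doc)
        doc = json.loads(text)
    comps = [
        Component(
            amplitude=e["c"],
            T2=e["T2"],
            T1=e.get("T1"),
            ADC=e.get("ADC"),
        )
        for e in doc["components"]
    ]
    grid = AcquisitionGrid(
        TE=np.asarray(doc["TE"], dtype=float),
        TI=np.asarray(doc["TI"], dtype=float) if "TI" in doc else None,
        b=np.asarray(doc["b"], dtype=float) if "b" in doc else None,
    )
    return MultiComponentModel(comps), grid
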