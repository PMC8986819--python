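"""Monte-Carlo simulation of noisy acquisitions and NLLS parameter recovery.

Each realization adds i.i.d. Gaussian noise to the noise-free signal,
draws an initial guess uniformly within a relative window around the true
parameters, and minimizes the sum of squared residuals over all grid
points with an unconstrained Levenberg-Marquardt iteration supplied with
the analytic Jacobian.  For 2D/3D tensors the objective is the squared
Frobenius norm, identical to the 2-norm objective on the vectorized data.

Because the components of a mixture model are exchangeable, fitted
parameter sets are relabeled before any statistics are taken: components
are sorted by ascending fitted T2, carrying their amplitudes (and T1/ADC
values) with them.  Sample means and SDs over noise realizations are then
directly comparable with the linearized covariance predictions.

Randomness: one master seed spawns an independent substream pair (noise
draw, initial guess) per realization via ``numpy.random.SeedSequence``, so
summaries are bitwise reproducible and extending the realization count
leaves earlier draws unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .models import (
    AcquisitionGrid,
    eval_signal,
    Dimensionality,
    MultiComponentModel,
    ParamLayout,
    SignalArray,
    jacobian_from_params,
    model_to_params,
    signal_from_params,
    split_params,
    vectorize,
)
from .stability import NoiseSpec

__all__ = [
    "FitConfig",
    "FitResult",
    "MCSummary",
    "add_noise",
    "fit_nlls",
    "run_mc",
    "relabel_params",
    "equal_time_snr",
    "fit_monoexponential",
]


@dataclass(frozen=True)
class FitConfig:
    """Controls for the NLLS fitter and the Monte-Carlo driver.

    ``init_fraction`` is the relative half-width of the uniform window
    around the true parameters from which initial guesses are drawn.
    ``amplitude_constraint`` reparameterizes a two-component fit as
    (c1, 1-c1), enforcing c1+c2=1; used by the synthetic experiment
    pathway, off by default for simulation sweeps.
    """

    init_fraction: float = 0.10
    max_iterations: int = 2000
    xtol: float = 1e-10
    ftol: float = 1e-10
    gtol: float = 1e-10
    seed: int = 0
    amplitude_constraint: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.init_fraction < 1:
            raise ValueError("init_fraction must lie in (0, 1)")
        if min(self.xtol, self.ftol, self.gtol) <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True, eq=False)
class FitResult:
    """One NLLS fit: relabeled parameters plus convergence diagnostics."""

    params: np.ndarray
    layout: ParamLayout
    residual_norm: float
    converged: bool
    n_iterations: int
    init_used: np.ndarray
    message: str = ""


@dataclass(frozen=True, eq=False)
class MCSummary:
    """Per-realization fitted parameters and their summary statistics.

    ``mean``/``sd`` are computed over converged realizations only;
    ``failure_count`` records the rest, and ``flagged`` marks a failure
    rate above 5%.
    """

    per_realization: pd.DataFrame
    mean: np.ndarray
    sd: np.ndarray
    layout: ParamLayout
    n_realizations: int
    snr_used: float | None
    sigma_used: float
    failure_count: int

    @property
    def flagged(self) -> bool:
        return self.failure_count > 0.05 * self.n_realizations

    def sd_by_label(self) -> dict[str, float]:
        return dict(zip(self.layout.labels, self.sd.tolist()))

    def mean_by_label(self) -> dict[str, float]:
        return dict(zip(self.layout.labels, self.mean.tolist()))

    def to_json_summary(self) -> dict:
        return {
            "labels": list(self.layout.labels),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "n_realizations": self.n_realizations,
            "snr": self.snr_used,
            "sigma": self.sigma_used,
            "failure_count": self.failure_count,
            "flagged": self.flagged,
        }


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def add_noise(
    signal: SignalArray,
    noise: NoiseSpec,
    rng: np.random.Generator,
) -> SignalArray:
    """Add i.i.d. zero-mean Gaussian noise of SD sigma at every grid point.

    sigma is resolved from ``noise`` against this signal (so for an
    SNR-specified level the reference must be the noiseless signal).
    The input is not modified.
    """
    sigma = noise.resolve_sigma(signal.values)
    noisy = signal.values + rng.normal(0.0, sigma, size=signal.values.shape)
    return SignalArray(values=noisy, grid=signal.grid)


# ---------------------------------------------------------------------------
# relabeling
# ---------------------------------------------------------------------------

def relabel_params(
    params: np.ndarray, dimensionality: Dimensionality, n: int
) -> np.ndarray:
    """Sort fitted components by ascending T2, permuting every attribute
    block coherently.

    Ties on T2 break by T1, then ADC, then amplitude, mirroring the
    canonical model ordering.  Works on raw fitted vectors, which may
    contain negative values.
    """
    blocks = split_params(params, dimensionality, n)
    keys = [blocks["c"]]
    if dimensionality.has_ADC:
        keys.append(blocks["ADC"])
    if dimensionality.has_T1:
        keys.append(blocks["T1"])
    keys.append(blocks["T2"])
    order = np.lexsort(tuple(keys))  # last key (T2) is primary
    layout = ParamLayout(n, dimensionality)
    out = np.empty_like(np.asarray(params, dtype=float))
    for k, blk in enumerate(layout.blocks):
        out[k * n : (k + 1) * n] = blocks[blk][order]
    return out


# ---------------------------------------------------------------------------
# nonlinear least squares
# ---------------------------------------------------------------------------

def _constrained_maps(
    dimensionality: Dimensionality, n: int
) -> tuple[Callable[[np.ndarray], np.ndarray], Callable[[np.ndarray], np.ndarray], np.ndarray]:
    """Reparameterization for the c1 + c2 = 1 constraint (n = 2 only).

    Returns (expand, reduce, chain) where ``expand`` maps the reduced
    vector (c2 dropped) to the full one, ``reduce`` the reverse, and
    ``chain`` is the constant d(full)/d(reduced) matrix used to project
    the analytic Jacobian.
    """
    if n != 2:
        raise ValueError("amplitude_constraint requires exactly 2 components")
    layout = ParamLayout(n, dimensionality)
    N = layout.N
    keep = [i for i in range(N) if i != 1]  # drop c2

    def expand(q: np.ndarray) -> np.ndarray:
        p = np.empty(N)
        p[keep] = q
        p[1] = 1.0 - q[0]
        return p

    def reduce(p: np.ndarray) -> np.ndarray:
        return np.asarray(p, dtype=float)[keep]

    chain = np.zeros((N, N - 1))
    for col, i in enumerate(keep):
        chain[i, col] = 1.0
    chain[1, 0] = -1.0  # dc2/dc1
    return expand, reduce, chain


def fit_nlls(
    data: SignalArray,
    grid: AcquisitionGrid,
    dimensionality: Dimensionality,
    init: np.ndarray,
    config: FitConfig = FitConfig(),
) -> FitResult:
    """Levenberg-Marquardt fit of the multicomponent model to noisy data.

    Minimizes the squared residual over all grid points (Frobenius norm
    for tensors, equivalently the 2-norm of the vectorized residual).
    Unconstrained by default: fitted values may be negative and are
    retained; the result is relabeled so fitted T2 values ascend.
    Optimizer failure is reported via ``converged=False``, never raised.
    """
    layout = ParamLayout(_infer_n(init, dimensionality), dimensionality)
    n = layout.n
    d = vectorize(data.values)
    init = np.asarray(init, dtype=float)

    if config.amplitude_constraint:
        expand, reduce, chain = _constrained_maps(dimensionality, n)

        def residuals(q: np.ndarray) -> np.ndarray:
            return (
                signal_from_params(expand(q), grid, dimensionality, n).reshape(-1)
                - d
            )

        def jac(q: np.ndarray) -> np.ndarray:
            return jacobian_from_params(expand(q), grid, dimensionality, n) @ chain

        x0 = reduce(init)
    else:
        expand = None

        def residuals(p: np.ndarray) -> np.ndarray:
            return (
                signal_from_params(p, grid, dimensionality, n).reshape(-1) - d
            )

        def jac(p: np.ndarray) -> np.ndarray:
            return jacobian_from_params(p, grid, dimensionality, n)

        x0 = init

    try:
        res = least_squares(
            residuals,
            x0,
            jac=jac,
            method="lm",
            xtol=config.xtol,
            ftol=config.ftol,
            gtol=config.gtol,
            max_nfev=config.max_iterations,
        )
        fitted = expand(res.x) if expand is not None else res.x
        converged = bool(res.success)
        n_iter = int(res.nfev)
        cost = float(2.0 * res.cost)  # least_squares cost is 0.5 * ||r||^2
        message = res.message
    except Exception as exc:  # numerical blow-up inside the model/optimizer
        fitted = np.full(layout.N, np.nan)
        converged = False
        n_iter = 0
        cost = np.nan
        message = f"{type(exc).__name__}: {exc}"

    if converged and np.all(np.isfinite(fitted)):
        fitted = relabel_params(fitted, dimensionality, n)
    return FitResult(
        params=fitted,
        layout=layout,
        residual_norm=cost,
        converged=converged,
        n_iterations=n_iter,
        init_used=init,
        message=message,
    )


def _infer_n(init: np.ndarray, dimensionality: Dimensionality) -> int:
    size = np.asarray(init).size
    per = dimensionality.n_attrs
    if size % per:
        raise ValueError(
            f"init length {size} is not a multiple of {per} for {dimensionality}"
        )
    return size // per


# ---------------------------------------------------------------------------
# Monte-Carlo driver
# ---------------------------------------------------------------------------

def run_mc(
    model: MultiComponentModel,
    grid: AcquisitionGrid,
    noise: NoiseSpec,
    n_realizations: int,
    config: FitConfig = FitConfig(),
) -> MCSummary:
    """Noise-propagation experiment: repeat (noise draw, init draw, fit).

    For each realization a fresh Gaussian noise vector is added to the
    noiseless signal and the fit is started from a uniform draw within
    ``+/- init_fraction`` of the true parameters.  Statistics (mean, SD
    per parameter) are over converged realizations; failures are counted.
    Fully reproducible from ``config.seed``.
    """
    if n_realizations < 2:
        raise ValueError("need at least 2 realizations")
    clean = eval_signal(model, grid)
    sigma = noise.resolve_sigma(clean.values)
    truth = model_to_params(model)
    dim = model.dimensionality
    layout = ParamLayout(model.n, dim)

    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(n_realizations)

    rows = []
    failures = 0
    for r, ss in enumerate(streams):
        noise_ss, init_ss = ss.spawn(2)
        noise_rng = np.random.default_rng(noise_ss)
        init_rng = np.random.default_rng(init_ss)

        noisy = clean.values + noise_rng.normal(0.0, sigma, size=clean.values.shape)
        lo = truth * (1.0 - config.init_fraction)
        hi = truth * (1.0 + config.init_fraction)
        init = init_rng.uniform(np.minimum(lo, hi), np.maximum(lo, hi))

        fit = fit_nlls(
            SignalArray(values=noisy, grid=grid), grid, dim, init, config
        )
        if not fit.converged:
            failures += 1
        row = {"realization": r, "converged": fit.converged}
        row.update(dict(zip(layout.labels, fit.params.tolist())))
        row["residual_norm"] = fit.residual_norm
        rows.append(row)

    table = pd.DataFrame(rows)
    ok = table[table["converged"]]
    values = ok[list(layout.labels)].to_numpy(dtype=float)
    mean = values.mean(axis=0) if len(ok) else np.full(layout.N, np.nan)
    sd = (
        values.std(axis=0, ddof=1)
        if len(ok) >= 2
        else np.full(layout.N, np.nan)
    )
    return MCSummary(
        per_realization=table,
        mean=mean,
        sd=sd,
        layout=layout,
        n_realizations=n_realizations,
        snr_used=noise.snr,
        sigma_used=sigma,
        failure_count=failures,
    )


def equal_time_snr(snr_nd: float, n_indirect: int) -> float:
    """SNR granted to the 1D experiment in an equal-time comparison.

    A higher-dimensional acquisition spends ``n_indirect`` times longer
    than one 1D readout; averaging that many 1D acquisitions instead
    raises SNR by sqrt(n_indirect): SNR_1D = SNR_nD * sqrt(n_indirect).
    """
    if n_indirect < 1:
        raise ValueError("n_indirect must be >= 1")
    return float(snr_nd) * float(np.sqrt(n_indirect))


# ---------------------------------------------------------------------------
# monoexponential calibration fits
# ---------------------------------------------------------------------------

def fit_monoexponential(
    data: np.ndarray,
    times: np.ndarray,
    kind: str = "T2-decay",
    init: tuple[float, float, float] | None = None,
) -> tuple[float, float, float, bool]:
    """Three-parameter monoexponential calibration fit.

    ``kind='T2-decay'`` fits ``A + M0*exp(-t/T2)`` (CPMG imaging series);
    ``kind='T1-saturation'`` fits ``A + M0*(1-exp(-t/T1))`` (progressive
    saturation with repetition time t=TR).  The offset A absorbs the
    Rician noise floor of magnitude imaging data.  Returns
    ``(A, M0, time_constant, converged)``; non-convergence is reported,
    not raised.
    """
    data = np.asarray(data, dtype=float)
    times = np.asarray(times, dtype=float)
    if times.size < 4:
        raise ValueError("need at least 4 time points for a 3-parameter fit")
    if kind == "T2-decay":
        def f(p: np.ndarray) -> np.ndarray:
            A, M0, tau = p
            return A + M0 * np.exp(-times / tau)
    elif kind == "T1-saturation":
        def f(p: np.ndarray) -> np.ndarray:
            A, M0, tau = p
            return A + M0 * (1.0 - np.exp(-times / tau))
    else:
        raise ValueError(f"unknown kind {kind!r}")

    if init is None:
        span = float(data.max() - data.min()) or 1.0
        tau0 = float(np.median(times))
        if kind == "T2-decay":
            init = (float(data.min()), span, tau0)
        else:
            init = (float(data.min()), span, tau0)
    try:
        res = least_squares(
            lambda p: f(p) - data, np.asarray(init, float), method="lm"
        )
        A, M0, tau = res.x
        return float(A), float(M0), float(tau), bool(res.success)
    except Exception:
        return np.nan, np.nan, np.nan, False
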