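"""Linearized covariance and conditioning of multiexponential fitting.

For additive i.i.d. Gaussian noise of standard deviation sigma, the
covariance of a linear least-squares estimate with design matrix G is
``(G^T G)^-1 sigma^2``.  Linearizing the nonlinear relaxometry model about
the true parameters replaces G by the Jacobian B of the vectorized signal,
giving the Cramer-Rao-style local covariance ``(B^T B)^-1 sigma^2``; its
diagonal holds the per-parameter variances, and the 2-norm condition number
of B quantifies how strongly noise is amplified into parameter error.

The covariance is computed from an SVD of the design matrix rather than by
forming and inverting the normal equations, which preserves accuracy
precisely where it matters most here: near component coalescence, where
the condition number grows without bound.  A matrix whose smallest singular
value falls below ``RANK_RTOL`` times the largest is declared singular; its
report carries ``condition_number = inf`` and an all-NaN covariance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
import numpy as np

from .models import (
    AcquisitionGrid,
    JacobianMatrix,
    MultiComponentModel,
    ParamLayout,
    eval_jacobian,
    eval_signal,
    jacobian_from_params,
)

__all__ = [
    "RANK_RTOL",
    "NoiseSpec",
    "StabilityReport",
    "linear_covariance",
    "nonlinear_covariance",
    "condition_number",
]

# relative singular-value cutoff below which B is declared rank-deficient
RANK_RTOL = 1e-12


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise level, given either as SNR or as sigma directly.

    SNR is the ratio of the maximum noise-free signal amplitude (max |S|
    over the analysis grid; inversion-recovery signals are signed) to the
    noise standard deviation, so ``sigma = max|S| / snr`` once a reference
    signal is available.
    """

    snr: float | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        if (self.snr is None) == (self.sigma is None):
            raise ValueError("specify exactly one of snr or sigma")
        if self.snr is not None and not self.snr > 0:
            raise ValueError(f"snr must be > 0, got {self.snr}")
        if self.sigma is not None and not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    def resolve_sigma(self, reference_signal: np.ndarray) -> float:
        """Noise SD in signal units, resolved against a noiseless signal."""
        if self.sigma is not None:
            return float(self.sigma)
        peak = float(np.max(np.abs(reference_signal)))
        if peak == 0.0:
            raise ValueError("reference signal is identically zero")
        return peak / float(self.snr)


@dataclass(frozen=True, eq=False)
class StabilityReport:
    """Linearized covariance, per-parameter SDs and cond(B) for one setting.

    ``singular`` flags numerical rank deficiency; then ``condition_number``
    is +inf and ``covariance``/``sd`` are NaN (the covariance is undefined,
    exactly as at exact component coalescence).
    """

    covariance: np.ndarray
    sd: np.ndarray
    condition_number: float
    param_layout: ParamLayout
    sigma_used: float
    singular: bool = False

    def sd_by_label(self) -> dict[str, float]:
        return dict(zip(self.param_layout.labels, self.sd.tolist()))

    def to_json(self) -> str:
        doc = {
            "labels": list(self.param_layout.labels),
            "covariance": np.where(
                np.isfinite(self.covariance), self.covariance, None
            ).tolist(),
            "sd": [s if np.isfinite(s) else None for s in self.sd.tolist()],
            "condition_number": self.condition_number
            if np.isfinite(self.condition_number)
            else "inf",
            "sigma": self.sigma_used,
            "singular": self.singular,
        }
        return json.dumps(doc, indent=2)

    def to_csv_row(self) -> dict[str, float]:
        """Flat record for sweep tables: one sd column per parameter."""
        row: dict[str, float] = {
            f"sd_{lab}": val for lab, val in self.sd_by_label().items()
        }
        row["condition_number"] = self.condition_number
        row["sigma"] = self.sigma_used
        row["singular"] = float(self.singular)
        return row


def _report_from_matrix(
    B: np.ndarray, sigma: float, layout: ParamLayout
) -> StabilityReport:
    M, N = B.shape
    if M < N:
        raise ValueError(
            f"need at least as many measurements as parameters (M={M} < N={N})"
        )
    # economic SVD: cov = V diag(1/s^2) V^T * sigma^2
    _, s, Vt = np.linalg.svd(B, full_matrices=False)
    if s[0] == 0.0 or s[-1] < RANK_RTOL * s[0]:
        nan = np.full((N, N), np.nan)
        return StabilityReport(
            covariance=nan,
            sd=np.full(N, np.nan),
            condition_number=np.inf,
            param_layout=layout,
            sigma_used=sigma,
            singular=True,
        )
    cov = (Vt.T / s**2) @ Vt * sigma**2
    cov = 0.5 * (cov + cov.T)  # symmetrize away rounding
    return StabilityReport(
        covariance=cov,
        sd=np.sqrt(np.diag(cov)),
        condition_number=float(s[0] / s[-1]),
        param_layout=layout,
        sigma_used=sigma,
    )


def linear_covariance(
    design_matrix: np.ndarray,
    sigma: float,
    layout: ParamLayout | None = None,
) -> StabilityReport:
    """Covariance ``(G^T G)^-1 sigma^2`` of a linear least-squares fit.

    ``layout`` is optional labelling; anonymous columns get a generic
    single-block layout when the column count is not a layout multiple.
    """
    G = np.asarray(design_matrix, dtype=float)
    if G.ndim != 2:
        raise ValueError("design matrix must be 2-D")
    if layout is None:
        layout = _anonymous_layout(G.shape[1])
    return _report_from_matrix(G, float(sigma), layout)


class _GenericLayout(ParamLayout):
    """Fallback labelling p1..pN for matrices without relaxometry meaning."""

    def __init__(self, N: int):
        object.__setattr__(self, "n", N)
        object.__setattr__(self, "dimensionality", None)

    @property
    def N(self) -> int:  # type: ignore[override]
        return self.n

    @property
    def labels(self) -> tuple[str, ...]:  # type: ignore[override]
        return tuple(f"p{i + 1}" for i in range(self.n))


def _anonymous_layout(N: int) -> ParamLayout:
    return _GenericLayout(N)


def nonlinear_covariance(
    model: MultiComponentModel,
    grid: AcquisitionGrid,
    noise: NoiseSpec,
    linearization_point: np.ndarray | None = None,
) -> StabilityReport:
    """Linearized covariance of NLLS estimates for ``model`` on ``grid``.

    The Jacobian is evaluated at the model's own (true) parameters, the
    standard choice for this local analysis; ``linearization_point``
    overrides that for diagnostics (e.g. linearizing at a fitted point).
    sigma is resolved from ``noise`` against the noiseless signal on the
    same grid.
    """
    signal = eval_signal(model, grid)
    sigma = noise.resolve_sigma(signal.values)
    layout = ParamLayout(model.n, model.dimensionality)
    if linearization_point is None:
        B = eval_jacobian(model, grid).entries
    else:
        B = jacobian_from_params(
            np.asarray(linearization_point, dtype=float),
            grid,
            model.dimensionality,
            model.n,
        )
    return _report_from_matrix(B, sigma, layout)


def condition_number(B: JacobianMatrix | np.ndarray) -> float:
    """2-norm condition number of B: ratio of extreme singular values.

    Returns +inf when the smallest singular value is below the relative
    rank tolerance.
    """
    entries = B.entries if isinstance(B, JacobianMatrix) else np.asarray(B, float)
    s = np.linalg.svd(entries, compute_uv=False)
    if s[0] == 0.0 or s[-1] < RANK_RTOL * s[0]:
        return float(np.inf)
    return float(s[0] / s[-1])
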