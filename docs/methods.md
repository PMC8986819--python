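# Methods

## Signal models

A sample is a discrete mixture of `n` monoexponential pools.  Pool `i`
has amplitude `cᵢ` (dimensionless), transverse relaxation time `T₂ᵢ`
(ms), and optionally longitudinal relaxation time `T₁ᵢ` (ms) and
apparent diffusion coefficient `ADCᵢ` (mm²/ms).  On an acquisition grid
of echo times `TE` (direct dimension), inversion times `TI`, and
diffusion weightings `b` (ms/mm², indirect dimensions) the noise-free
signal is separable per pool:

    S = Σᵢ cᵢ · e^(−TE/T₂ᵢ) · (1 − 2 e^(−TI/T₁ᵢ)) · e^(−b·ADCᵢ),

with the inversion-recovery and diffusion factors present only when the
corresponding axis exists.  The IR factor is signed — it is negative for
TI < T₁ ln 2 and exactly zero at TI = T₁ ln 2 — because the data are
assumed phased along the real axis (single-channel spectroscopic
acquisition), which also keeps the noise model Gaussian rather than
Rician.

Signals are real tensors of shape `(n_b, n_TI, n_TE)` (absent leading
axes dropped).  The fixed vectorization is C order: b slowest, then TI,
then TE fastest.  Nothing downstream depends on this order (BᵀB and the
Frobenius objective are row-permutation invariant), but fixing it makes
row maps reproducible and testable.

The flat parameter vector groups attributes in blocks, components in
canonical order within each block: amplitudes, then T₁s (if present),
then T₂s, then ADCs.  For two components in 2D this is
`(c₁, c₂, T₁₁, T₁₂, T₂₁, T₂₂)`.  Canonical component order is ascending
T₂, with ties broken by T₁, then ADC, then amplitude; the same rule
relabels fitted parameter sets, so mixture label-switching cannot
contaminate summary statistics.

The Jacobian of the vectorized signal is computed in closed form from
the separable kernel derivatives and is validated in the test suite
against a central finite-difference oracle (step `10⁻⁶·max(1, |pₗ|)`)
over randomized models and grids in all three dimensionalities.

## Linearized stability theory

For i.i.d. Gaussian noise of SD σ, linear least squares with design
matrix G has Cov(p*) = (GᵀG)⁻¹σ².  Linearizing the nonlinear model about
the true parameters p₀ replaces G with the Jacobian B evaluated at p₀,
giving the local (Cramér–Rao) covariance

    Cov(p*) = (BᵀB)⁻¹ σ²,

whose diagonal holds the per-parameter variances.  The linearization
point is always the true model by default (an optional argument allows
linearizing at a fitted point for diagnostics).  The 2-norm condition
number of B — the ratio of its extreme singular values — measures how
strongly data noise is amplified into parameter error.

Numerics: the covariance is computed from an economic SVD of B, never by
forming and inverting BᵀB, since accuracy matters most exactly where the
problem approaches singularity.  B is declared numerically rank-deficient
when its smallest singular value is below `10⁻¹²` times the largest; the
report then carries `condition_number = inf`, an all-NaN covariance, and
a `singular` flag rather than an exception, so sweeps can pass through
coalescence points.

SNR is defined as max |S| over the analysis grid divided by σ, using the
absolute value because IR signals are signed.  For a given SNR, σ is
resolved once against the noiseless signal and never re-estimated from
noisy data.

### Units and conditioning

The condition number of B is unit-dependent because the parameter vector
mixes dimensionless amplitudes with time constants.  All package I/O
uses milliseconds.  For conditioning *comparisons across
dimensionalities* (`sweep_condition_numbers`), the Jacobian is evaluated
with times rescaled to seconds (b and ADC kept in ms/mm² and mm²/ms, so
b·ADC is unchanged): then every parameter — amplitudes ~O(1), times
0.04–2 s, ADC O(1) — sits on a comparable scale, and the conditioning
structure of the problem is visible.  Under this convention
cond(B₂D)/cond(B₁D) is 1.0001–1.0006 at T₁ equality for the standard
parameter sets and drops well below 1 as the T₁ ratio departs from
unity, with cond(B₃D) ≤ cond(B₂D) pointwise and near-equality on the
ADC₂ = ADC₁ slice.  Evaluated naively in ms the picture inverts: the
O(10³) scale gap between amplitudes and T₁ values dominates the singular
spectrum and the 2D condition number exceeds the 1D one everywhere.
`time_scale=1` reproduces that behavior if wanted.

### A note on which SDs peak at indirect-dimension equality

Across the T₁₂ ∈ [800, 1200] ms sweep (T₁₁ = 1000 ms, T₂ = 45/60 ms),
the amplitude SDs and T₂ SDs attain their maximum where the T₁ values
coincide, as does cond(B) — the central instability result.  The T₁ SDs
themselves, however, attain a pronounced *minimum* there (≈4× below the
sweep endpoints).  This is a genuine property of the model, not a
numerical artifact: the package's linearized covariance and an
independent Monte-Carlo run at SNR 10⁶ agree on it to within a few
percent per point, under both fixed-σ and fixed-SNR conventions.  When
the two T₁s coincide the shared inversion-recovery factor is maximally
constrained by all n_TI × n_TE points, so each individual T₁ is easy to
pin down even though the components themselves (amplitudes, T₂s) become
maximally confusable.  The acceptance suite records the corresponding
blanket "every parameter peaks at equality" check as failing by design;
the module tests assert the verified behavior.

## Monte-Carlo engine

Each realization adds i.i.d. Gaussian noise of SD σ to the noiseless
signal and fits the model by unconstrained Levenberg–Marquardt
(`scipy.optimize.least_squares`, `method="lm"`) with the analytic
Jacobian, minimizing the squared Frobenius norm over all grid points
(identical to the 2-norm on the vectorized residual).  Initial guesses
are drawn uniformly within ±10% (`init_fraction`, configurable) of the
true parameters.  Negative fitted values are permitted and retained — no
clamping — and results are relabeled by ascending fitted T₂.  Stopping
tolerances default to `xtol = ftol = gtol = 10⁻¹⁰` with a 2000-evaluation
cap; these are documented configuration values, not claims of
equivalence to any particular optimizer implementation.

Optimizer failures are reported (`converged=False`) rather than raised;
failed realizations are excluded from means/SDs but counted, and a
failure rate above 5% flags the summary.  Randomness: a single master
seed spawns an independent `SeedSequence` substream pair (noise draw,
init draw) per realization, so results are bitwise reproducible and
extending the realization count leaves earlier draws unchanged.

Near-coalescent settings (T₂ ratio ≈ 1, or T₁ equality in 2D) produce
heavy-tailed estimate distributions: a small fraction of fits converge
to a coalesced local minimum far from truth, which can dominate sample
SDs even at very high SNR.  This is a property of the estimation
problem, not of the optimizer settings; sample SDs in those regimes
should be read qualitatively.

The amplitude constraint c₁ + c₂ = 1 (used by the synthetic experiment
pathway, matching how two-pool phantom data are conventionally analyzed)
is implemented by reparameterizing to (c₁, 1−c₁) with the chain rule
applied to the analytic Jacobian; it is off for all simulation sweeps.

An equal-time comparison grants the 1D experiment an SNR of
`SNR_nD · √n_indirect`, since the time of one nD acquisition buys
n_indirect averaged 1D acquisitions.  In the equal-T₁ limit the 2D
experiment is then slightly *less* efficient than 1D — the linearized
shared-parameter SD ratio is 1.27 for the standard TI schedule — because
the IR modulation spends part of the signal near its null while the 1D
experiment integrates at full amplitude; the 2D advantage appears, and
quickly becomes decisive, as the T₁ ratio departs from 1.

Monoexponential three-parameter calibration fits
(`A + M₀·e^(−TE/T₂)` and `A + M₀·(1 − e^(−TR/T₁))`) mirror the imaging
fits used to characterize phantom compartments; the offset A absorbs the
Rician floor of magnitude images and is *not* part of the relaxometry
forward models.

## Sweep defaults

The standard simulation designs, all overridable per run:

| quantity | default | count |
| --- | --- | --- |
| TE | 8…512 ms, step 8 ms | 64 |
| TI | 50…4850 ms, step 200 ms | 25 |
| b  | 0…2 ms/mm², step 0.25 | 9 |
| SNR (1D sweeps) | 10⁴ | — |
| SNR (2D MC) | 400 (equal-time 1D: 2000) | — |
| noise realizations | 1000 | — |

1D coalescence sweep: (c₁, c₂, T₂₁) = (0.3, 0.7, 60 ms), T₂₂ swept.
2D sweeps: T₁₁ = 1000 ms, T₁₂ swept over 800–1200 ms; the analytic
preset stores T₂ = (60, 45) ms and the Monte-Carlo preset (45, 60) ms —
both conventional presentations of the same physical family (canonical
relabeling maps between them), shipped verbatim rather than reconciled.
3D: (c₁, c₂, T₂₁, T₂₂, T₁₁, ADC₁) = (0.7, 0.3, 45 ms, 60 ms, 1000 ms,
1.5 mm²/ms), sweeping (T₁₂, ADC₂).  A swept value that coalesces with
the fixed component yields a singular-flagged row, never an aborted
sweep.  Histogram binning for plots follows the Freedman–Diaconis rule;
raw per-realization values are always retained in the output tables.

## Synthetic two-gel experiment

The emulation reproduces the *design* of a two-compartment
CuSO₄-doped agarose gel study: gel model (c₁, c₂) = (0.47, 0.53),
(T₂₁, T₂₂) = (36.3, 45.9) ms, (T₁₁, T₁₂) = (157, 405) ms (T₁ ratio
≈ 2.6); a 1D CPMG pathway of 2048 echoes at TE = 0.4…819.2 ms with
SNR ≈ 9000 (signal averaging folded into the SNR rather than simulated
echo-by-echo — only the resulting noise level matters under the additive
Gaussian model); a 2D IR-CPMG pathway with 24 inversion times from 15 ms
to 2 s at SNR ≈ 2000; 100 repeats per pathway; constrained (c₁+c₂ = 1)
NLLS per repeat.

The 24-step TI schedule is known only to be "nonlinear"; the default is
geometric spacing (the standard IR schedule), with an explicit-list
override.  Because the true schedule is unknown, emulated SD magnitudes
are not expected to match measured ones numerically — only the
qualitative 1D-vs-2D ordering is meaningful, and that ordering is strong
(the 2D pathway's amplitude and T₂ SDs come out ≈ 20× smaller despite
its 4.5× SNR disadvantage).

What the generator emulates: the acquisition geometry, the signed
phased-real IR signal, i.i.d. Gaussian noise, repeat structure.  What it
does not: T₂/T₁ *distributions* within each gel (pools are
delta-function monoexponentials), stimulated echoes, B₁ inhomogeneity,
slice profiles, noise correlations, drift, or any imaging aspects.
Passing tests therefore demonstrate the statistical mechanism — higher
dimensions stabilize the inverse Laplace transform — not instrumental
fidelity.

The near-degeneracy demonstration (`lanczos_demo`) evaluates the classic
pair S₁ = 0.2 e^(−t/20) + 0.8 e^(−t/150), S₂ = 0.28 e^(−t/40) +
0.70 e^(−t/163): their maximum gap on t ∈ [0, 400] is 0.02 (at t = 0,
the amplitude-sum deficit), i.e. 2% of full scale for entirely different
components.

## Problem sizes used in the checked runs

The shipped test suite and acceptance script use 1000 realizations for
1D Monte-Carlo agreement checks, 300 per arm for the equal-time 1D/2D
comparison, and 100 repeats for the gel study; the full suite runs in
about a minute on one CPU.  All are configuration values, and every
random quantity derives from an explicit seed.

## Known limitations

* The linearized covariance is a local theory: it assumes the fit lands
  near truth and becomes unreliable exactly where its own condition
  number says so.  No global analysis of the NLLS objective is
  attempted.
* No NNLS / regularized spectrum estimation; the estimator is parametric
  NLLS with a known component count.
* Gaussian noise only — no Rician magnitude-data analysis and no bias
  analysis under non-Gaussian noise.
* Condition-number magnitudes depend on the unit convention (see above);
  only orderings and ratios within a convention are meaningful.
* Sweeps hard-code two components; forward evaluation and Jacobians
  accept arbitrary n.
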