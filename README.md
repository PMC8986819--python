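# relaxstab

Stability analysis of multiexponential decay parameter estimation in one,
two, and three dimensions, in the setting of magnetic resonance
relaxometry.

## The problem

Many physical signals decay as a sum of exponentials,

    S(t) = Σᵢ cᵢ exp(−t / τᵢ),

and one wants the component amplitudes `cᵢ` and time constants `τᵢ`.
Recovering them from noisy samples is a discrete inverse Laplace transform
and is severely ill-posed: visibly indistinguishable curves can arise
from entirely different component sets, so fitted parameters are wildly
unstable under noise whenever the time constants are close.

Magnetic resonance relaxometry can, almost uniquely among experimental
techniques, *extend this problem into higher dimensions*: an
inversion-recovery preparation adds T₁ sensitivity to the CPMG T₂ decay,

    S(TI, TE) = Σᵢ cᵢ (1 − 2 e^(−TI/T₁ᵢ)) e^(−TE/T₂ᵢ),

and diffusion weighting adds a third axis `e^(−b·ADCᵢ)`.  When the
components differ in the indirect dimension (T₁ or ADC ratio away from
1), the extra dimension supplies discriminating information: the
condition number of the model Jacobian drops and parameter estimates
stabilize dramatically — even on an *equal-time* basis, where the 1D
experiment is granted a √n_indirect SNR advantage.

This package implements that analysis as a tested pipeline for
researchers in quantitative MR (and anyone fitting multiexponential
decays):

* **Forward models and analytic Jacobians** for n-component T₂, T₁–T₂
  and T₁–T₂–ADC signals (`relaxstab.models`).
* **Linearized (Cramér–Rao style) covariance**: Cov(p*) = (BᵀB)⁻¹σ² with
  B the Jacobian at the true parameters, per-parameter SDs, and the
  2-norm condition number of B (`relaxstab.stability`).
* **Monte-Carlo experiments**: Gaussian noise realizations, unconstrained
  Levenberg–Marquardt fits with the analytic Jacobian, component
  relabeling by ascending fitted T₂, and distribution summaries
  (`relaxstab.montecarlo`).
* **Parameter sweeps** reproducing the canonical stability experiments:
  1D coalescence, 2D T₁-separation, condition-number orderings across
  dimensionalities, 3D (T₁, ADC) surfaces (`relaxstab.sweeps`).
* **A synthetic two-gel phantom study**: repeated noisy 1D CPMG
  (2048 echoes, SNR ≈ 9000) and 2D IR-CPMG (24 inversion times,
  SNR ≈ 2000) acquisitions of a two-component CuSO₄-doped agarose gel
  model, fitted with the c₁+c₂ = 1 constraint
  (`relaxstab.experiment`).
* **Config-driven CLI** with full provenance capture (`relaxstab.cli`).

## Worked example

Linearized theory versus Monte-Carlo for a 2D T₁–T₂ experiment with
well-separated T₁ values (T₁ ratio 2), at SNR 400:

```python
import numpy as np
from relaxstab import (
    AcquisitionGrid, Component, FitConfig, MultiComponentModel,
    NoiseSpec, nonlinear_covariance, run_mc,
)

model = MultiComponentModel([
    Component(amplitude=0.3, T2=45.0, T1=1000.0),
    Component(amplitude=0.7, T2=60.0, T1=500.0),
])
grid = AcquisitionGrid(
    TE=np.arange(8.0, 513.0, 8.0),        # 64 echoes
    TI=np.arange(50.0, 4851.0, 200.0),    # 25 inversion times
)
noise = NoiseSpec(snr=400.0)

report = nonlinear_covariance(model, grid, noise)
print("linearized SDs:", {k: f"{v:.3g}" for k, v in report.sd_by_label().items()})
print("cond(B) =", f"{report.condition_number:.4g}")

mc = run_mc(model, grid, noise, n_realizations=500, config=FitConfig(seed=1))
print("Monte-Carlo SDs:", {k: f"{v:.3g}" for k, v in mc.sd_by_label().items()})
print("failures:", mc.failure_count)
```

prints

```
linearized SDs: {'c_1': '0.0255', 'c_2': '0.0262', 'T1_1': '35.7', 'T1_2': '6.21', 'T2_1': '0.705', 'T2_2': '0.337'}
cond(B) = 1.672e+05
Monte-Carlo SDs: {'c_1': '0.0247', 'c_2': '0.0254', 'T1_1': '35.1', 'T1_2': '6.07', 'T2_1': '0.695', 'T2_2': '0.327'}
failures: 0
```

The sample SDs of 500 independent noisy fits agree with the linearized
prediction to a few percent: at this T₁ separation the amplitudes are
recovered to ±0.025 and the T₂ values to well under a millisecond,
whereas an equal-time 1D experiment (SNR 2000) leaves the amplitude SDs
an order of magnitude larger (≈0.25 — run the `sweep2d` stage or the
acceptance script to see the comparison).

The same computations are available from the shell:

```sh
relaxstab demo-fig1 --out results          # near-degeneracy demonstration
relaxstab sweep1d   --out results --seed 1 # 1D coalescence sweep
relaxstab cond      --out results          # 1D/2D condition numbers
relaxstab analyze   --out results --seed 1 # synthetic two-gel study
```

Each stage writes a result CSV, a provenance JSON (config hash, seed,
effective grids), and a manifest; reruns with the same config are
byte-identical.

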