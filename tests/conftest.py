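import numpy as np
import pytest

from relaxstab import (
    AcquisitionGrid,
    Component,
    MultiComponentModel,
)


@pytest.fixture
def te64() -> np.ndarray:
    """Standard 1D echo-time grid: 8..512 ms in 8 ms steps."""
    return np.arange(8.0, 512.0 + 1e-9, 8.0)


@pytest.fixture
def ti25() -> np.ndarray:
    """Standard inversion-time grid: 50..4850 ms in 200 ms steps."""
    return np.arange(50.0, 4850.0 + 1e-9, 200.0)


@pytest.fixture
def grid_1d(te64) -> AcquisitionGrid:
    return AcquisitionGrid(TE=te64)


@pytest.fixture
def grid_2d(te64, ti25) -> AcquisitionGrid:
    return AcquisitionGrid(TE=te64, TI=ti25)


@pytest.fixture
def model_1d() -> MultiComponentModel:
    return MultiComponentModel(
        [Component(amplitude=0.3, T2=45.0), Component(amplitude=0.7, T2=60.0)]
    )


@pytest.fixture
def model_2d() -> MultiComponentModel:
    return MultiComponentModel(
        [
            Component(amplitude=0.3, T2=45.0, T1=1000.0),
            Component(amplitude=0.7, T2=60.0, T1=500.0),
        ]
    )


def random_model_and_grid(rng: np.random.Generator):
    """Random (model, grid) draw across all three dimensionalities.

    Small grids; parameters in physically plausible ranges so the
    finite-difference oracle is well-scaled.
    """
    dim = rng.integers(0, 3)
    n = int(rng.integers(1, 4))
    comps = []
    for _ in range(n):
        T1 = float(rng.uniform(100, 3000)) if dim >= 1 else None
        ADC = float(rng.uniform(0.1, 3.0)) if dim == 2 else None
        comps.append(
            Component(
                amplitude=float(rng.uniform(0.05, 1.0)),
                T2=float(rng.uniform(10, 300)),
                T1=T1,
                ADC=ADC,
            )
        )
    TE = np.sort(rng.uniform(1, 600, size=rng.integers(4, 9)))
    TI = np.sort(rng.uniform(10, 4000, size=rng.integers(3, 7))) if dim >= 1 else None
    b = np.sort(rng.uniform(0, 2, size=rng.integers(3, 6))) if dim == 2 else None
    return MultiComponentModel(comps), AcquisitionGrid(TE=TE, TI=TI, b=b)
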