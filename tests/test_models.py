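"""Forward-model and Jacobian correctness.

The finite-difference oracle used here was written against the signal
evaluator alone and is independent of the analytic derivative code path.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relaxstab import (
    AcquisitionGrid,
    Component,
    Dimensionality,
    MultiComponentModel,
    devectorize,
    eval_jacobian,
    eval_signal,
    model_grid_from_json,
    model_grid_to_json,
    model_to_params,
    params_to_model,
    vectorize,
)
from relaxstab.models import signal_from_params

from conftest import random_model_and_grid

TINY_TE = 1e-9  # TE must be positive; this is numerically t = 0


def fd_jacobian(model, grid, rel_step=1e-6):
    """Central finite differences of the vectorized signal."""
    p = model_to_params(model)
    dim, n = model.dimensionality, model.n
    J = np.zeros((grid.M, p.size))
    for l in range(p.size):
        h = rel_step * max(1.0, abs(p[l]))
        pp, pm = p.copy(), p.copy()
        pp[l] += h
        pm[l] -= h
        J[:, l] = (
            signal_from_params(pp, grid, dim, n)
            - signal_from_params(pm, grid, dim, n)
        ).reshape(-1) / (2 * h)
    return J


class TestSignal:
    @pytest.mark.parametrize(
        "amps, T2s, expected",
        [((0.2, 0.8), (20.0, 150.0), 1.0), ((0.28, 0.7), (40.0, 163.0), 0.98)],
    )
    def test_signal_at_time_zero_is_amplitude_sum(self, amps, T2s, expected):
        model = MultiComponentModel(
            [Component(amplitude=a, T2=t) for a, t in zip(amps, T2s)]
        )
        grid = AcquisitionGrid(TE=np.array([TINY_TE]))
        assert eval_signal(model, grid).values[0] == pytest.approx(expected, abs=1e-9)

    def test_inversion_null_cancels_component(self, te64):
        # at TI = T1 ln 2 the IR factor of that component is exactly zero
        T1_1 = 800.0
        model = MultiComponentModel(
            [
                Component(amplitude=0.4, T2=40.0, T1=T1_1),
                Component(amplitude=0.6, T2=90.0, T1=2000.0),
            ]
        )
        grid = AcquisitionGrid(TE=te64, TI=np.array([T1_1 * np.log(2.0)]))
        other_only = 0.6 * np.exp(-te64 / 90.0) * (
            1 - 2 * np.exp(-T1_1 * np.log(2.0) / 2000.0)
        )
        np.testing.assert_allclose(
            eval_signal(model, grid).values[0], other_only, rtol=1e-12
        )

    def test_long_TI_limit_recovers_pure_decay(self, te64, model_2d):
        TI = 20000.0
        grid = AcquisitionGrid(TE=te64, TI=np.array([TI]))
        decay_1d = MultiComponentModel(
            [Component(amplitude=c.amplitude, T2=c.T2) for c in model_2d.components]
        )
        s2 = eval_signal(model_2d, grid).values[0]
        s1 = eval_signal(decay_1d, AcquisitionGrid(TE=te64)).values
        tol = 2 * np.exp(-TI / max(c.T1 for c in model_2d.components))
        assert np.max(np.abs(s2 - s1)) <= tol

    def test_zero_b_reduces_to_2d_signal(self, te64, ti25):
        model_3d = MultiComponentModel(
            [
                Component(amplitude=0.3, T2=45.0, T1=1000.0, ADC=1.5),
                Component(amplitude=0.7, T2=60.0, T1=500.0, ADC=0.5),
            ]
        )
        model_2d = MultiComponentModel(
            [
                Component(amplitude=0.3, T2=45.0, T1=1000.0),
                Component(amplitude=0.7, T2=60.0, T1=500.0),
            ]
        )
        g3 = AcquisitionGrid(TE=te64, TI=ti25, b=np.array([0.0, 1.0]))
        g2 = AcquisitionGrid(TE=te64, TI=ti25)
        np.testing.assert_allclose(
            eval_signal(model_3d, g3).values[0],
            eval_signal(model_2d, g2).values,
            rtol=1e-14,
        )

    @pytest.mark.parametrize(
        "grid_kwargs, model_fixture, match",
        [
            (dict(TI=np.array([100.0])), "model_1d", "lack T1"),
            (dict(), "model_2d", "lacks a TI axis"),
        ],
    )
    def test_dimensionality_mismatch_names_missing_attribute(
        self, te64, grid_kwargs, model_fixture, match, request
    ):
        model = request.getfixturevalue(model_fixture)
        grid = AcquisitionGrid(TE=te64, **grid_kwargs)
        with pytest.raises(ValueError, match=match):
            eval_signal(model, grid)

    def test_separability_against_triple_loop(self):
        # explicit triple loop over a 3x3x3 grid, summed per component
        rng = np.random.default_rng(42)
        model = MultiComponentModel(
            [
                Component(0.5, 30.0, 800.0, 1.2),
                Component(0.4, 80.0, 1500.0, 0.4),
            ]
        )
        TE = np.sort(rng.uniform(5, 300, 3))
        TI = np.sort(rng.uniform(20, 3000, 3))
        b = np.sort(rng.uniform(0, 2, 3))
        grid = AcquisitionGrid(TE=TE, TI=TI, b=b)
        expected = np.zeros((3, 3, 3))
        for l in range(3):
            for k in range(3):
                for j in range(3):
                    for c in model.components:
                        expected[l, k, j] += (
                            c.amplitude
                            * np.exp(-TE[j] / c.T2)
                            * (1 - 2 * np.exp(-TI[k] / c.T1))
                            * np.exp(-b[l] * c.ADC)
                        )
        np.testing.assert_allclose(
            eval_signal(model, grid).values, expected, rtol=1e-13
        )

    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=25, deadline=None)
    def test_signal_linear_in_amplitudes(self, scale):
        base = MultiComponentModel(
            [Component(0.3, 45.0), Component(0.7, 60.0)]
        )
        scaled = MultiComponentModel(
            [Component(0.3 * scale, 45.0), Component(0.7 * scale, 60.0)]
        )
        grid = AcquisitionGrid(TE=np.arange(8.0, 513.0, 8.0))
        np.testing.assert_allclose(
            eval_signal(scaled, grid).values,
            scale * eval_signal(base, grid).values,
            rtol=1e-13,
        )

    def test_pure_decay_strictly_decreasing_in_TE(self, model_1d, grid_1d):
        values = eval_signal(model_1d, grid_1d).values
        assert np.all(np.diff(values) < 0)

    def test_coalesced_components_collapse_to_single_pool(self, te64):
        many = MultiComponentModel(
            [Component(0.2, 75.0), Component(0.5, 75.0), Component(0.3, 75.0)]
        )
        one = MultiComponentModel([Component(1.0, 75.0)])
        grid = AcquisitionGrid(TE=te64)
        np.testing.assert_allclose(
            eval_signal(many, grid).values, eval_signal(one, grid).values,
            rtol=1e-14,
        )


class TestJacobian:
    def test_amplitude_column_is_pure_decay(self, model_1d, grid_1d):
        B = eval_jacobian(model_1d, grid_1d)
        col = B.layout.index("c", 0)
        np.testing.assert_allclose(
            B.entries[:, col],
            np.exp(-grid_1d.TE / model_1d.components[0].T2),
            rtol=1e-14,
        )

    def test_coalescence_makes_amplitude_columns_identical(self, grid_1d):
        model = MultiComponentModel(
            [Component(0.3, 60.0), Component(0.7, 60.0)]
        )
        B = eval_jacobian(model, grid_1d).entries
        np.testing.assert_array_equal(B[:, 0], B[:, 1])
        assert np.linalg.matrix_rank(B) < B.shape[1]

    def test_analytic_matches_finite_differences_over_random_draws(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            model, grid = random_model_and_grid(rng)
            B = eval_jacobian(model, grid).entries
            F = fd_jacobian(model, grid)
            # absolute floor for entries far below the O(1) signal scale,
            # where central differences are pure cancellation noise
            # (FD rounding is ~eps*|S|/2h ~ 5e-11, well under 1e-5 * 1e-4)
            denom = np.maximum(np.abs(F), 1e-4)
            assert np.max(np.abs(B - F) / denom) < 1e-5


class TestVectorization:
    def test_round_trip_restores_tensor(self, te64, ti25, model_2d):
        grid = AcquisitionGrid(TE=te64[:3], TI=ti25[:2])
        sig = eval_signal(model_2d, grid)
        flat = vectorize(sig)
        assert flat.shape == (6,)
        np.testing.assert_array_equal(devectorize(flat, grid), sig.values)

    def test_1d_vectorization_is_identity(self, model_1d, grid_1d):
        sig = eval_signal(model_1d, grid_1d)
        np.testing.assert_array_equal(vectorize(sig), sig.values)

    def test_TI_is_slower_than_TE_in_flat_order(self):
        # element (TI index k=1, TE index j=0) must land at flat index n_TE
        tensor = np.arange(6.0).reshape(2, 3)
        grid = AcquisitionGrid(
            TE=np.array([1.0, 2.0, 3.0]), TI=np.array([10.0, 20.0])
        )
        flat = vectorize(tensor)
        assert flat[3] == tensor[1, 0]
        np.testing.assert_array_equal(devectorize(flat, grid), tensor)


class TestModelContainer:
    def test_components_are_canonically_ordered(self):
        model = MultiComponentModel(
            [Component(0.7, 150.0), Component(0.3, 20.0)]
        )
        assert [c.T2 for c in model.components] == [20.0, 150.0]
        assert [c.amplitude for c in model.components] == [0.3, 0.7]

    def test_param_vector_round_trip(self, model_2d):
        p = model_to_params(model_2d)
        rebuilt = params_to_model(p, model_2d.dimensionality, model_2d.n)
        assert rebuilt == model_2d

    def test_param_layout_for_two_component_2d_model(self, model_2d):
        p = model_to_params(model_2d)
        # (c1, c2, T1_1, T1_2, T2_1, T2_2); component 1 has the smaller T2
        np.testing.assert_array_equal(
            p, [0.3, 0.7, 1000.0, 500.0, 45.0, 60.0]
        )

    def test_mixed_attribute_presence_rejected(self):
        with pytest.raises(ValueError, match="all components"):
            MultiComponentModel(
                [Component(0.5, 40.0, T1=900.0), Component(0.5, 90.0)]
            )

    def test_json_round_trip(self, model_2d, grid_2d):
        doc = model_grid_to_json(model_2d, grid_2d)
        model, grid = model_grid_from_json(doc)
        assert model == model_2d
        np.testing.assert_array_equal(grid.TE, grid_2d.TE)
        np.testing.assert_array_equal(grid.TI, grid_2d.TI)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(amplitude=-0.1, T2=50.0),
            dict(amplitude=0.5, T2=0.0),
            dict(amplitude=0.5, T2=50.0, T1=-3.0),
            dict(amplitude=0.5, T2=50.0, T1=100.0, ADC=-1.0),
        ],
    )
    def test_invalid_component_rejected(self, bad):
        with pytest.raises(ValueError):
            Component(**bad)

    def test_non_increasing_grid_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            AcquisitionGrid(TE=np.array([8.0, 8.0, 16.0]))
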