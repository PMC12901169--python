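"""Coupler model: error matrix construction and VOP transformation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dicosar import (
    CouplerModel,
    SMatrix,
    VOPSet,
    build_error_matrix,
    custom_error_matrix,
    evaluate_sar,
    linear_directivity,
    ratio_to_percent,
    single_channel_worst_case,
    transform_vops,
)

from conftest import random_hermitian


class TestLinearDirectivity:
    @pytest.mark.parametrize(
        "db,expected",
        [(0.0, 1.0), (20.0, 10.0), (25.0, 17.7828)],
    )
    def test_voltage_db_convention(self, db, expected):
        assert linear_directivity(db) == pytest.approx(expected, abs=5e-5)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            linear_directivity(np.inf)


class TestCouplerModel:
    def test_attenuation_below_one_rejected(self):
        with pytest.raises(ValueError, match="attenuation"):
            CouplerModel(25.0, attenuation_linear=0.5)

    def test_per_channel_directivity_vector(self):
        c = CouplerModel(np.array([20.0, 40.0]))
        np.testing.assert_allclose(c.inverse_directivity(2), [0.1, 0.01])

    def test_per_channel_length_mismatch(self):
        with pytest.raises(ValueError, match="channels"):
            CouplerModel(np.array([20.0, 40.0])).inverse_directivity(3)


class TestBuildErrorMatrix:
    def test_zero_smatrix_gives_identity(self):
        M = build_error_matrix(SMatrix(np.zeros((3, 3))), CouplerModel(25.0, 1.2))
        np.testing.assert_array_equal(M.values, np.eye(3))

    def test_infinite_directivity_limit(self, rng):
        S = SMatrix(0.5 * (rng.standard_normal((3, 3)) + 1j * rng.standard_normal((3, 3))))
        M = build_error_matrix(S, CouplerModel(2000.0, 0.7))
        np.testing.assert_allclose(M.values, np.eye(3), atol=1e-90)

    def test_single_channel_opposed_phase(self):
        # 1 + e^{i pi} * 0.5/10 = 0.95
        M = build_error_matrix(SMatrix([[0.5]]), CouplerModel(20.0, np.pi))
        assert M.values[0, 0] == pytest.approx(0.95, abs=1e-12)

    def test_two_pi_periodicity_and_attenuation(self, rng):
        S = SMatrix(0.3 * (rng.standard_normal((2, 2)) + 1j * rng.standard_normal((2, 2))))
        c1 = CouplerModel(25.0, 0.7, attenuation_linear=1.5)
        c2 = CouplerModel(25.0, 0.7 + 2 * np.pi, attenuation_linear=1.5)
        np.testing.assert_allclose(
            build_error_matrix(S, c1).values, build_error_matrix(S, c2).values, atol=1e-14
        )
        # mu scales the deviation from identity
        c3 = CouplerModel(25.0, 0.7, attenuation_linear=3.0)
        dev1 = build_error_matrix(S, c1).values - np.eye(2)
        dev3 = build_error_matrix(S, c3).values - np.eye(2)
        np.testing.assert_allclose(dev3, dev1 * 1.5 / 3.0, atol=1e-14)

    def test_deviation_shrinks_monotonically_with_directivity(self, rng):
        S = SMatrix(0.5 * (rng.standard_normal((4, 4)) + 1j * rng.standard_normal((4, 4))))
        norms = []
        for db in [20, 40, 60, 100, 200]:
            M = build_error_matrix(S, CouplerModel(float(db), 0.3))
            norms.append(np.linalg.norm(M.values - np.eye(4)))
        assert all(a > b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-9


class TestTransformVops:
    def test_identity_error_matrix_is_noop(self, rng):
        vops = VOPSet(np.stack([random_hermitian(rng, 3) for _ in range(4)]))
        out = transform_vops(vops, custom_error_matrix(np.eye(3)))
        np.testing.assert_allclose(out.matrices, vops.matrices, atol=1e-15)

    def test_scalar_error_matrix_scales_quadratically(self, rng):
        vops = VOPSet(random_hermitian(rng, 3)[None])
        out = transform_vops(vops, custom_error_matrix(0.5 * np.eye(3)))
        np.testing.assert_allclose(out.matrices, 0.25 * vops.matrices, atol=1e-15)

    def test_quadratic_form_equals_transformed_excitation(self, rng):
        # x^H (M^H Q M) x == (Mx)^H Q (Mx) for random instances
        Q = random_hermitian(rng, 2)
        vops = VOPSet(Q[None])
        Mv = rng.standard_normal((2, 2)) + 1j * rng.standard_normal((2, 2))
        out = transform_vops(vops, custom_error_matrix(Mv))
        for _ in range(100):
            x = rng.standard_normal(2) + 1j * rng.standard_normal(2)
            lhs = evaluate_sar(out, x)[0]
            rhs = evaluate_sar(vops, Mv @ x)[0]
            assert lhs == pytest.approx(rhs, rel=1e-10, abs=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        vops = VOPSet(random_hermitian(rng, 3)[None])
        with pytest.raises(ValueError, match="channels"):
            transform_vops(vops, custom_error_matrix(np.eye(2)))

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 2**16), n=st.integers(2, 16))
    def test_preserves_hermiticity_and_psd(self, seed, n):
        r = np.random.default_rng(seed)
        vops = VOPSet(np.stack([random_hermitian(r, n) for _ in range(3)]))
        Mv = r.standard_normal((n, n)) + 1j * r.standard_normal((n, n))
        out = transform_vops(vops, custom_error_matrix(Mv))  # VOPSet re-validates
        for Q in out:
            w = np.linalg.eigvalsh(Q)
            assert w[0] >= -1e-10 * max(w[-1], 1e-30)


class TestSingleChannelWorstCase:
    def test_matched_channel_no_error(self):
        assert single_channel_worst_case(0.0, 25.0) == 1.0

    def test_full_reflection_20db(self):
        # numeric oracle: minimize |1 + e^{i phi}/10|^2 over a dense phi grid
        phi = np.linspace(0, 2 * np.pi, 10**6)
        oracle = 1.0 / np.min(np.abs(1 + np.exp(1j * phi) * 0.1) ** 2)
        assert single_channel_worst_case(1.0, 20.0) == pytest.approx(oracle, rel=1e-9)
        assert single_channel_worst_case(1.0, 20.0) == pytest.approx(1 / 0.81, rel=1e-12)

    def test_full_reflection_25db_percent(self):
        r = single_channel_worst_case(1.0, 25.0)
        assert ratio_to_percent(r) == pytest.approx(10.93, abs=0.005)

    def test_vanishing_measured_signal_rejected(self):
        with pytest.raises(ValueError, match="vanish"):
            single_channel_worst_case(1.0, -1.0)

    def test_strictly_monotone_in_reflection_and_directivity(self):
        s_grid = np.linspace(0, 0.99, 25)
        r_s = [single_channel_worst_case(s, 25.0) for s in s_grid]
        assert all(a < b for a, b in zip(r_s, r_s[1:]))
        d_grid = np.linspace(10, 60, 25)
        r_d = [single_channel_worst_case(0.8, d) for d in d_grid]
        assert all(a > b for a, b in zip(r_d, r_d[1:]))


class TestPercentConventions:
    def test_both_conventions(self):
        assert ratio_to_percent(1.25, "of-actual") == pytest.approx(20.0)
        assert ratio_to_percent(1.25, "ratio-minus-one") == pytest.approx(25.0)
        with pytest.raises(ValueError):
            ratio_to_percent(1.25, "bogus")
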