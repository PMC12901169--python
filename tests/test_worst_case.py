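"""Worst-case solver: real embedding, SDR with certificates, sweeps."""

import numpy as np
import pytest

from dicosar import (
    CouplerModel,
    SMatrix,
    SynthArraySpec,
    UnboundedError,
    VOPSet,
    build_error_matrix,
    custom_error_matrix,
    generalized_eig_ratio,
    max_ratio_at_phase,
    max_ratio_for_error_matrix,
    phase_sweep,
    power_error_at_phase,
    power_error_sweep,
    real_embed,
    synth_smatrix,
    synth_vops,
    transform_vops,
)

from conftest import random_hermitian


class TestRealEmbed:
    def test_real_symmetric_gives_block_diagonal(self, rng):
        Q = random_hermitian(rng, 3).real
        Q = 0.5 * (Q + Q.T)
        emb = real_embed(Q).values
        np.testing.assert_allclose(emb[:3, :3], Q)
        np.testing.assert_allclose(emb[3:, 3:], Q)
        np.testing.assert_allclose(emb[:3, 3:], 0, atol=1e-15)

    def test_scalar_case(self):
        np.testing.assert_allclose(real_embed([[2.5]]).values, 2.5 * np.eye(2))

    def test_quadratic_forms_agree(self, rng):
        Q = random_hermitian(rng, 4, psd=False)
        emb = real_embed(Q).values
        for _ in range(100):
            x = rng.standard_normal(4) + 1j * rng.standard_normal(4)
            z = np.concatenate([x.real, x.imag])
            assert z @ emb @ z == pytest.approx(
                np.real(x.conj() @ Q @ x), rel=1e-10, abs=1e-12
            )

    def test_symmetry_invariant(self, rng):
        emb = real_embed(random_hermitian(rng, 5)).values
        np.testing.assert_allclose(emb, emb.T, atol=1e-12)

    def test_non_hermitian_rejected(self, rng):
        A = rng.standard_normal((3, 3)) + 1j * rng.standard_normal((3, 3))
        with pytest.raises(ValueError, match="Hermitian"):
            real_embed(A)


class TestMaxRatioAtPhase:
    def test_ideal_measurement_unit_ratio(self, zero_smatrix):
        vops = synth_vops(3, 4, 3, seed=3)
        res = max_ratio_at_phase(vops, zero_smatrix, CouplerModel(25.0, 0.8))
        assert res.ratio == pytest.approx(1.0, abs=1e-6)

    def test_scalar_forced_ratio(self):
        # measured VOP = 0.25 forces |x|^2 <= 4, actual VOP = 1 -> ratio 4
        vops = VOPSet(np.array([[[1.0]]]))
        res = max_ratio_for_error_matrix(vops, custom_error_matrix([[0.5]]))
        assert res.ratio == pytest.approx(4.0, rel=1e-7)
        assert res.argmax_vop_index == 0

    def test_result_certificate_is_consistent(self, small_instance):
        S, vops = small_instance
        coupler = CouplerModel(25.0, 1.0)
        res = max_ratio_at_phase(vops, S, coupler)
        # extracted excitation is feasible and achieves ratio*(1-gap)
        measured = transform_vops(vops, build_error_matrix(S, coupler))
        x = res.argmax_excitation
        forms = [np.real(x.conj() @ Q @ x) for Q in measured]
        assert max(forms) <= 1 + 1e-6
        achieved = max(np.real(x.conj() @ Q @ x) for Q in vops)
        assert achieved >= res.ratio * (1 - res.certificate_gap) * (1 - 1e-9)
        assert res.solver_status.startswith("optimal")

    def test_scale_invariance(self, small_instance):
        S, vops = small_instance
        coupler = CouplerModel(25.0, 2.0)
        base = max_ratio_at_phase(vops, S, coupler).ratio
        scaled = VOPSet(vops.matrices * 37.5)
        assert max_ratio_at_phase(scaled, S, coupler).ratio == pytest.approx(
            base, rel=1e-9
        )

    def test_congruence_consistency(self, small_instance):
        # solving with the coupler model equals solving with the error
        # matrix applied upfront through the generic entry point
        S, vops = small_instance
        coupler = CouplerModel(22.0, 0.4)
        M = build_error_matrix(S, coupler)
        r1 = max_ratio_at_phase(vops, S, coupler).ratio
        r2 = max_ratio_for_error_matrix(vops, M).ratio
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_singular_custom_error_matrix_unbounded(self, rng):
        vops = VOPSet(np.stack([np.eye(2, dtype=complex)]))
        M = custom_error_matrix([[1.0, 0.0], [0.0, 0.0]])  # kills channel 2
        with pytest.raises(UnboundedError):
            max_ratio_for_error_matrix(vops, M)

    def test_harmless_common_null_space_proceeds(self):
        # actual SAR also vanishes on the dead channel: finite answer
        Q = np.diag([1.0, 0.0]).astype(complex)
        vops = VOPSet(Q[None])
        M = custom_error_matrix(np.diag([0.5, 0.0]))
        res = max_ratio_for_error_matrix(vops, M)
        assert res.ratio == pytest.approx(4.0, rel=1e-7)

    def test_sniffer_coil_style_error_matrix(self):
        # identity plus one small off-diagonal correlation: finite ratio >= 1
        vops = synth_vops(2, 3, 2, seed=11)
        M = custom_error_matrix([[1.0, 0.05], [0.0, 1.0]])
        res = max_ratio_for_error_matrix(vops, M)
        assert np.isfinite(res.ratio) and res.ratio >= 1.0 - 1e-9


class TestPhaseSweep:
    def test_flat_at_one_for_decoupled_array(self, zero_smatrix):
        vops = synth_vops(3, 3, 3, seed=5)
        sweep = phase_sweep(vops, zero_smatrix, 25.0, n_steps=16)
        np.testing.assert_allclose(sweep.ratios, 1.0, atol=1e-6)
        assert sweep.peak_ratio == pytest.approx(1.0, abs=1e-6)

    def test_default_grid_is_360_points(self):
        # only checks grid construction, so use the 1-channel closed case
        sweep = phase_sweep(VOPSet(np.ones((1, 1, 1))), SMatrix([[0.2]]), 25.0)
        assert len(sweep.phases_rad) == 360
        assert sweep.phases_rad[0] == 0.0
        assert sweep.phases_rad[-1] == pytest.approx(2 * np.pi * 359 / 360)

    def test_single_channel_matches_closed_form(self):
        from dicosar import ratio_to_percent, single_channel_worst_case

        sweep = phase_sweep(VOPSet(np.ones((1, 1, 1))), SMatrix([[0.8]]), 25.0, n_steps=720)
        expected = single_channel_worst_case(0.8, 25.0)
        assert sweep.peak_ratio == pytest.approx(expected, rel=1e-5)
        assert sweep.peak_percent() == pytest.approx(
            ratio_to_percent(expected), abs=1e-3
        )

    def test_invalid_steps_rejected(self, zero_smatrix):
        with pytest.raises(ValueError):
            phase_sweep(synth_vops(3, 1, 3, seed=0), zero_smatrix, 25.0, n_steps=0)


class TestPowerError:
    def test_zero_smatrix_ratio_one(self, zero_smatrix):
        assert power_error_at_phase(zero_smatrix, CouplerModel(25.0, 0.0)) == pytest.approx(1.0)

    def test_single_channel_scalar_arithmetic(self):
        # M = 1 - 10^(-25/20) = 0.943766; ratio = 1/M^2
        ratio = power_error_at_phase(SMatrix([[1.0]]), CouplerModel(25.0, np.pi))
        m = 1 - 10 ** (-1.25)
        assert m == pytest.approx(0.943766, abs=5e-7)
        assert ratio == pytest.approx(1 / m**2, rel=1e-12)
        assert ratio == pytest.approx(1.12272, abs=5e-6)

    def test_at_least_one_for_passive_arrays(self):
        for seed in range(5):
            S = synth_smatrix(SynthArraySpec(4, 0.3, 0.2, seed=seed))
            r = power_error_at_phase(S, CouplerModel(25.0, seed * 0.9))
            assert r >= 1.0 - 1e-12

    def test_unitary_smatrix_peak_approaches_closed_form(self):
        # total reflection: worst case aligns all channels, scalar closed form
        n = 3
        rng = np.random.default_rng(42)
        Qr, _ = np.linalg.qr(rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n)))
        sweep = power_error_sweep(SMatrix(Qr), 40.0, n_steps=720)
        d = 10 ** (40 / 20)
        expected_pct = (1 - (1 - 1 / d) ** 2) * 100
        assert sweep.peak_percent() == pytest.approx(expected_pct, rel=1e-3)

    def test_periodicity_of_sweep(self):
        S = synth_smatrix(SynthArraySpec(3, 0.4, 0.3, seed=9))
        s1 = power_error_sweep(S, 25.0, n_steps=24)
        # shifting all phases by 2*pi reproduces the same ratios
        ratios_shifted = [
            power_error_at_phase(S, CouplerModel(25.0, p + 2 * np.pi))
            for p in s1.phases_rad
        ]
        np.testing.assert_allclose(s1.ratios, ratios_shifted, rtol=1e-12)


class TestGeneralizedEigConsistency:
    def test_single_vop_equals_pencil_eigenvalue(self, rng):
        # with one constraint the SDR is exact: largest generalized
        # eigenvalue of (Q, M^H Q M)
        for seed in range(5):
            vops = synth_vops(3, 1, 3, seed=seed)
            S = synth_smatrix(SynthArraySpec(3, 0.4, 0.3, seed=seed + 50))
            coupler = CouplerModel(25.0, 0.5 + seed)
            res = max_ratio_at_phase(vops, S, coupler)
            M = build_error_matrix(S, coupler).values
            expected = generalized_eig_ratio(vops[0], M.conj().T @ vops[0] @ M)
            assert res.ratio == pytest.approx(expected, rel=1e-6)
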