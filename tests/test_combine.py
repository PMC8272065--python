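"""The four combination methods, checked against independent oracles.

Oracles are deliberately naive: generalized least squares via explicit
normal equations, the leading singular triplet via power iteration on
X^H X, and the per-point recombination via a loop of one-unknown
least-squares solves.
"""

import numpy as np
import pytest

from mrscombine.datamodel import AcquisitionBlock, AcquisitionMeta, CoilMatrix, to_frequency
from mrscombine.combine import (
    SensitivityField,
    average_block,
    combine_assvd,
    combine_brown,
    combine_gls,
    combine_svd,
    combine_wsvd,
    estimate_sensitivity_field,
    pick_naa_sensitivity,
    smooth_sensitivity,
)
from mrscombine.noise import NoiseModel, identity_noise_model
from mrscombine.simulate import (
    LineModel,
    SpectralLine,
    make_coil_profile,
    make_correlated_psi,
    simulate_block,
)

from conftest import corr, random_rank1


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def gls_normal_equations(x, psi, s):
    """Brute-force generalized least squares, row by row of the point axis."""
    psi_inv = np.linalg.inv(psi)
    gain = 1.0 / (s.conj() @ psi_inv @ s)
    return np.array([gain * (s.conj() @ psi_inv @ x[:, n]) for n in range(x.shape[1])])


def power_iteration_rank1(x, iters=2000):
    """Leading singular triplet by power iteration on X^H X."""
    v = np.ones(x.shape[1], dtype=complex) / np.sqrt(x.shape[1])
    for _ in range(iters):
        v = x.conj().T @ (x @ v)
        v /= np.linalg.norm(v)
    sigma = np.linalg.norm(x @ v)
    u = x @ v / sigma
    return u, sigma, v


def per_point_ls(block_data, sens, whitener):
    """One-unknown least squares per (average, point), averaged over averages."""
    c, a_count, n = block_data.shape
    m = np.zeros((a_count, n), dtype=complex)
    for a in range(a_count):
        for i in range(n):
            sw = whitener @ sens[:, a, i]
            xw = whitener @ block_data[:, a, i]
            m[a, i], *_ = np.linalg.lstsq(sw[:, None], xw, rcond=None)[0]
    return m.mean(axis=0)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestAverageBlock:
    def test_single_average_passthrough(self, meta_small, rng):
        meta = AcquisitionMeta(2000.0, 64, 2, 1)
        data = rng.standard_normal((2, 1, 64)) + 0j
        out = average_block(AcquisitionBlock(data, meta))
        np.testing.assert_array_equal(out.data, data[:, 0, :])

    def test_opposite_averages_cancel(self):
        meta = AcquisitionMeta(2000.0, 16, 2, 2)
        x = np.ones((2, 16), complex)
        out = average_block(AcquisitionBlock(np.stack([x, -x], axis=1), meta))
        np.testing.assert_array_equal(out.data, np.zeros((2, 16)))

    def test_noise_reduction_scales_with_averages(self, rng):
        meta = AcquisitionMeta(2000.0, 256, 2, 128)
        noise = rng.standard_normal(meta.shape) + 1j * rng.standard_normal(meta.shape)
        out = average_block(AcquisitionBlock(noise, meta))
        assert np.std(out.data) == pytest.approx(np.std(noise) / np.sqrt(128), rel=0.1)


class TestBrown:
    def test_single_coil_unit_weight(self):
        row = np.array([[1.0, 2.0, 3.0]], dtype=complex)
        out = combine_brown(CoilMatrix(row))
        np.testing.assert_array_equal(out.fid, row[0])

    def test_two_coil_hand_example(self):
        # weights are the first points: 1*r1 + 2*r2
        x = np.array([[1.0, 5.0, 7.0], [2.0, 11.0, 13.0]], dtype=complex)
        out = combine_brown(CoilMatrix(x))
        np.testing.assert_array_equal(out.fid, x[0] + 2 * x[1])

    def test_bilinear_scaling(self, rng):
        x = rng.standard_normal((3, 8)) + 1j * rng.standard_normal((3, 8))
        a, b = combine_brown(CoilMatrix(x)), combine_brown(CoilMatrix(2 * x))
        np.testing.assert_allclose(b.fid, 4 * a.fid, rtol=1e-12)

    def test_degenerate_weights_rejected(self):
        x = np.zeros((2, 4), complex)
        x[:, 1] = 1.0
        with pytest.raises(ValueError, match="first"):
            combine_brown(CoilMatrix(x))

    def test_conjugate_weights_recover_rank1(self, rng):
        # conj(s_c m(0)) weights align coil phases, so the sum is exactly m
        s, m, x = random_rank1(rng, 4, 32)
        out = combine_brown(CoilMatrix(x), conjugate_weights=True)
        assert corr(out.fid, m) >= 1 - 1e-12


class TestGls:
    def test_unit_sensitivity_selects_coil(self, rng):
        x = rng.standard_normal((3, 16)) + 1j * rng.standard_normal((3, 16))
        out = combine_gls(CoilMatrix(x), identity_noise_model(3), np.array([1, 0, 0]))
        np.testing.assert_allclose(out.fid, x[0], atol=1e-12)

    def test_unbiased_on_noiseless_rank1(self, rng):
        s, m, x = random_rank1(rng, 4, 64)
        model = make_correlated_psi(4, 0.5, 1)
        out = combine_gls(CoilMatrix(x), model, s)
        assert np.max(np.abs(out.fid - m)) < 1e-10 * np.max(np.abs(m))

    def test_matches_normal_equations_oracle(self, rng):
        for trial in range(10):
            x = rng.standard_normal((2, 16)) + 1j * rng.standard_normal((2, 16))
            s = rng.standard_normal(2) + 1j * rng.standard_normal(2)
            psi = np.diag([1.0, 4.0]).astype(complex)
            out = combine_gls(CoilMatrix(x), NoiseModel.from_psi(psi), s)
            expected = gls_normal_equations(x, psi, s)
            np.testing.assert_allclose(out.fid, expected, atol=1e-10)

    def test_zero_sensitivity_rejected(self, rng):
        x = CoilMatrix(rng.standard_normal((2, 8)) + 0j)
        with pytest.raises(ValueError, match="zero"):
            combine_gls(x, identity_noise_model(2), np.zeros(2))


class TestPickNaaSensitivity:
    def _lorentzian_block(self, meta, profile):
        lines = LineModel([SpectralLine("NAA", 2.01, 1.0)])
        psi = identity_noise_model(meta.n_coils)
        block, _ = simulate_block(lines, meta, profile, psi, q=0, rng_seed=0)
        return average_block(block)

    def test_recovers_coil_ratio(self, meta_small):
        profile = np.array([1.0, 2.0 * np.exp(0.7j), 0.5, 1.0 + 0.3j])
        x = self._lorentzian_block(meta_small, profile)
        s = pick_naa_sensitivity(x, meta_small)
        ratios = s / s[0]
        np.testing.assert_allclose(ratios, profile / profile[0], rtol=1e-6)

    def test_zero_spectrum_gives_zero_vector(self, meta_small):
        x = CoilMatrix(np.zeros((4, meta_small.n_points), complex))
        s = pick_naa_sensitivity(x, meta_small)
        assert np.all(s == 0)

    def test_window_outside_axis_raises(self, meta_small, rng):
        x = CoilMatrix(rng.standard_normal((4, meta_small.n_points)) + 0j)
        with pytest.raises(ValueError):
            pick_naa_sensitivity(x, meta_small, center_ppm=90.0)


class TestSvd:
    def test_rank1_recovery(self, rng):
        s, m, x = random_rank1(rng, 4, 32)
        sol = combine_svd(CoilMatrix(x))
        assert corr(sol.combined, m) >= 1 - 1e-10
        assert corr(sol.sensitivity, s) >= 1 - 1e-10

    def test_gauge_first_point_real_nonnegative(self, rng):
        _, _, x = random_rank1(rng, 3, 16)
        sol = combine_svd(CoilMatrix(x))
        assert sol.combined[0].imag == pytest.approx(0.0, abs=1e-12)
        assert sol.combined[0].real >= 0

    def test_identity_input_tie_flagged(self):
        sol = combine_svd(CoilMatrix(np.eye(2, dtype=complex)))
        assert sol.degenerate
        outer = np.outer(sol.sensitivity, sol.combined)
        assert np.linalg.norm(outer) == pytest.approx(1.0, abs=1e-10)

    def test_best_rank1_matches_power_iteration(self, rng):
        for trial in range(10):
            x = rng.standard_normal((4, 8)) + 1j * rng.standard_normal((4, 8))
            sol = combine_svd(CoilMatrix(x))
            u, sigma, v = power_iteration_rank1(x)
            res_pkg = np.linalg.norm(x - np.outer(sol.sensitivity, sol.combined))
            res_oracle = np.linalg.norm(x - sigma * np.outer(u, v.conj()))
            assert abs(res_pkg - res_oracle) < 1e-10
            assert sol.sigma1 == pytest.approx(sigma, abs=1e-10)


class TestWsvd:
    def test_identity_psi_matches_plain_svd(self, rng):
        _, m, x = random_rank1(rng, 4, 32)
        x = x + 0.01 * (rng.standard_normal(x.shape) + 1j * rng.standard_normal(x.shape))
        plain = combine_svd(CoilMatrix(x))
        white = combine_wsvd(CoilMatrix(x), identity_noise_model(4))
        assert corr(white.fid, plain.combined) >= 1 - 1e-10

    def test_noiseless_rank1_recovery(self, rng):
        s, m, x = random_rank1(rng, 4, 64)
        model = make_correlated_psi(4, 0.6, 5)
        out = combine_wsvd(CoilMatrix(x), model)
        assert corr(out.fid, m) >= 1 - 1e-9

    def test_whitening_beats_plain_svd_under_correlated_noise(self, rng):
        # strongly coupled noise: whitening recovers the spectrum more
        # faithfully than plain SVD, on average over repeats
        model = make_correlated_psi(6, 0.8, 2)
        wins, trials = 0, 30
        for _ in range(trials):
            s, m, x = random_rank1(rng, 6, 128)
            from mrscombine.noise import generate_correlated_noise

            noise = generate_correlated_noise(model, 128, rng, exact_cov=True)
            noisy = x / np.linalg.norm(x) * 40 + noise
            plain = combine_svd(CoilMatrix(noisy)).combined
            white = combine_wsvd(CoilMatrix(noisy), model).fid
            wins += corr(white, m) > corr(plain, m)
        assert wins > trials / 2


class TestSensitivityField:
    def test_constant_sensitivity_recovered_noiseless(self, meta_small):
        profile = make_coil_profile(meta_small.n_coils, 3)
        lines = LineModel([SpectralLine("NAA", 2.01, 1.0), SpectralLine("Cr", 3.03, 0.8)])
        block, _ = simulate_block(
            lines, meta_small, profile, identity_noise_model(meta_small.n_coils), 0, 0
        )
        field = estimate_sensitivity_field(block, identity_noise_model(meta_small.n_coils))
        # each (a, n) column is the true profile up to one global gauge factor
        ref = field.raw[:, 0, 0]
        for a in (0, meta_small.n_averages - 1):
            cols = field.raw[:, a, :50]
            assert np.max(np.abs(cols - ref[:, None])) < 1e-8 * np.abs(ref).max()
        assert corr(ref, profile) >= 1 - 1e-9

    def test_zero_average_rejected(self, meta_small, rng):
        data = rng.standard_normal(meta_small.shape) + 0j
        data[:, 2, :] = 0
        block = AcquisitionBlock(data, meta_small)
        with pytest.raises(ValueError, match="average 2"):
            estimate_sensitivity_field(block, identity_noise_model(meta_small.n_coils))


class TestSmoothing:
    def _field(self, raw):
        return SensitivityField(raw=raw, smoothed=raw.copy(), kernel_size=1)

    def test_k1_is_identity(self, rng):
        raw = rng.standard_normal((2, 8, 16)) + 1j * rng.standard_normal((2, 8, 16))
        out = smooth_sensitivity(self._field(raw), 1)
        np.testing.assert_array_equal(out.smoothed, raw)

    def test_constant_preserved(self):
        raw = np.full((2, 9, 9), 3.0 - 2.0j)
        out = smooth_sensitivity(self._field(raw), 7)
        np.testing.assert_allclose(out.smoothed, raw, atol=1e-12)

    def test_linearity(self, rng):
        a = rng.standard_normal((1, 9, 9)) + 1j * rng.standard_normal((1, 9, 9))
        b = rng.standard_normal((1, 9, 9)) + 1j * rng.standard_normal((1, 9, 9))
        sm = lambda f: smooth_sensitivity(self._field(f), 3).smoothed
        np.testing.assert_allclose(sm(a + 2 * b), sm(a) + 2 * sm(b), atol=1e-12)

    def test_variance_reduction_law(self, rng):
        # k x k averaging divides the variance of white noise by about k^2
        k = 7
        raw = (rng.standard_normal((1, 200, 200)) + 1j * rng.standard_normal((1, 200, 200)))
        out = smooth_sensitivity(self._field(raw), k)
        interior = out.smoothed[0, 20:-20, 20:-20]
        reduction = np.var(raw) / np.var(interior)
        assert reduction == pytest.approx(k**2, rel=0.2)

    @pytest.mark.parametrize("k", [0, 2, 4, 11])
    def test_invalid_kernel_rejected(self, rng, k):
        raw = rng.standard_normal((1, 9, 32)) + 0j
        with pytest.raises(ValueError):
            smooth_sensitivity(self._field(raw), k)


class TestAssvd:
    def test_noiseless_exactness_any_kernel(self, meta_small):
        profile = make_coil_profile(meta_small.n_coils, 7)
        lines = LineModel([SpectralLine("NAA", 2.01, 1.0), SpectralLine("Cho", 3.19, 0.4)])
        model = identity_noise_model(meta_small.n_coils)
        block, truth = simulate_block(lines, meta_small, profile, model, 0, 0)
        for k in (1, 3, 7):
            out = combine_assvd(block, model, k=k)
            assert corr(out.fid, truth.clean_m) >= 1 - 1e-9

    def test_k1_matches_per_point_ls_oracle(self, rng):
        meta = AcquisitionMeta(2000.0, 4, 2, 2)
        s = np.array([1.0 + 0.2j, 0.5 - 0.4j])
        m = np.array([1.0, 0.8 - 0.1j, 0.5 + 0.2j, 0.3j])
        data = np.stack([np.outer(s, m)] * 2, axis=1)
        data += 0.01 * (rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape))
        block = AcquisitionBlock(data, meta)
        model = identity_noise_model(2)
        out = combine_assvd(block, model, k=1)
        field = estimate_sensitivity_field(block, model)
        oracle = per_point_ls(data, field.raw, model.whitener)
        # the package output carries the first-point phase gauge; remove it
        phase = oracle[0] / abs(oracle[0])
        np.testing.assert_allclose(out.fid, oracle / phase, atol=1e-8)

    def test_single_average_k1_agrees_with_wsvd(self, meta_small, rng):
        meta = AcquisitionMeta(2000.0, meta_small.n_points, 4, 1)
        s, m, x = random_rank1(rng, 4, meta.n_points)
        block = AcquisitionBlock(x[:, None, :], meta)
        model = identity_noise_model(4)
        assvd = combine_assvd(block, model, k=1)
        wsvd = combine_wsvd(CoilMatrix(x), model)
        assert corr(assvd.fid, wsvd.fid) >= 1 - 1e-6

    def test_global_phase_gauge_invariance(self, meta_small):
        profile = make_coil_profile(meta_small.n_coils, 9)
        lines = LineModel([SpectralLine("NAA", 2.01, 1.0)])
        model = make_correlated_psi(meta_small.n_coils, 0.3, 0)
        block, _ = simulate_block(lines, meta_small, profile, model, 1, 4)
        rotated = AcquisitionBlock(block.data * np.exp(0.9j), meta_small)
        for combiner in (
            lambda b: combine_assvd(b, model, k=3),
            lambda b: combine_wsvd(average_block(b), model),
            lambda b: combine_brown(average_block(b)),
        ):
            a = np.abs(to_frequency(combiner(block).fid))
            b = np.abs(to_frequency(combiner(rotated).fid))
            np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-9 * a.max())

    def test_even_kernel_rejected(self, meta_small, rng):
        data = rng.standard_normal(meta_small.shape) + 0j
        block = AcquisitionBlock(data, meta_small)
        with pytest.raises(ValueError):
            combine_assvd(block, identity_noise_model(meta_small.n_coils), k=4)


class TestRank1Exactness:
    """Every method recovers m up to a scalar on noiseless rank-1 input."""

    @pytest.mark.parametrize("method", ["svd", "wsvd", "gls", "assvd", "brown_conj"])
    def test_recovery(self, rng, method):
        s, m, x = random_rank1(rng, 4, 64)
        model = make_correlated_psi(4, 0.4, 6)
        if method == "svd":
            out = combine_svd(CoilMatrix(x)).combined
        elif method == "wsvd":
            out = combine_wsvd(CoilMatrix(x), model).fid
        elif method == "gls":
            out = combine_gls(CoilMatrix(x), model, s).fid
        elif method == "brown_conj":
            out = combine_brown(CoilMatrix(x), conjugate_weights=True).fid
        else:
            meta = AcquisitionMeta(2000.0, 64, 4, 2)
            block = AcquisitionBlock(np.stack([x, x], axis=1), meta)
            out = combine_assvd(block, model, k=1).fid
        assert corr(out, m) >= 1 - 1e-9
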