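import numpy as np
import pytest
import pywt

from mfecg import binomial_cascade, cascade_zeta, fbm
from mfecg.leaders import (Leaders, WaveletCoeffs, check_wavelet_adequacy,
                           compute_leaders, default_q_grid, direct_spectrum,
                           dwt_l1, hoelder_bounds, legendre_spectrum,
                           max_scale_index, multifractal_spectrum,
                           scaling_function, spectrum_features,
                           structure_functions)


def make_coeffs(arrays):
    return WaveletCoeffs(d=[np.asarray(a, float) for a in arrays],
                         wavelet="synthetic", n_vanishing=3, regularity=3.0,
                         n=2 * len(arrays[0]))


def leaders_oracle(arrays):
    """Exhaustive sup over every (j', k') whose dyadic interval lies inside
    the 3-lambda neighbourhood, straight from the definition."""
    out = []
    for j, d in enumerate(arrays, start=1):
        L = np.empty(len(d))
        for k in range(len(d)):
            lo, hi = (k - 1) * 2 ** j, (k + 2) * 2 ** j  # 3-lambda in samples
            best = -np.inf
            for jp, dp in enumerate(arrays[:j], start=1):
                for kp in range(len(dp)):
                    if kp * 2 ** jp >= lo and (kp + 1) * 2 ** jp <= hi:
                        best = max(best, dp[kp])
            L[k] = best
        out.append(L)
    return out


class TestMaxScaleIndex:
    @pytest.mark.parametrize("n,nv,expected", [
        (8192, 3, 10),
        (256, 3, 5),
        (14, 3, 1),
    ])
    def test_values(self, n, nv, expected):
        assert max_scale_index(n, nv) == expected

    def test_too_short_signal(self):
        with pytest.raises(ValueError):
            max_scale_index(7, 3)


class TestDwtL1:
    def test_constant_signal_has_zero_details(self):
        c = dwt_l1(np.full(1024, 4.2), "db3", j2=5)
        for d in c.d:
            assert np.abs(d).max() < 1e-10

    def test_db3_annihilates_quadratics(self):
        x = 3.0 * np.linspace(0, 1, 2048) ** 2 - 0.5
        c = dwt_l1(x, "db3", j2=6)
        for d in c.d:
            assert np.abs(d[2:-2]).max() < 1e-8

    def test_impulse_matches_convolution_oracle(self):
        """Coefficient magnitudes for a Kronecker impulse must equal a
        direct circular-convolution + decimation pyramid (compared as
        per-scale multisets; the decimation phase is convention)."""
        n = 256
        x = np.zeros(n)
        x[97] = 1.0
        j2 = 4
        c = dwt_l1(x, "db3", j2=j2)
        w = pywt.Wavelet("db3")
        lo = np.asarray(w.dec_lo)
        hi = np.asarray(w.dec_hi)
        # dwt_l1 subtracts the linear bridge; replicate it for the oracle
        a = x - x[0] - (x[-1] - x[0]) * np.arange(n) / (n - 1)
        for j in range(1, j2 + 1):
            m = len(a)
            conv_hi = np.array([np.dot(hi, a[(i - np.arange(len(hi))) % m])
                                for i in range(m)])
            conv_lo = np.array([np.dot(lo, a[(i - np.arange(len(lo))) % m])
                                for i in range(m)])
            want = np.sort(np.abs(conv_hi[1::2])) * 2 ** (-j / 2)
            got = np.sort(c.d[j - 1])
            np.testing.assert_allclose(got, want, atol=1e-12)
            # carry the approximation band on; the periodized pyramid takes
            # the odd decimation phase with a one-slot circular shift
            a = np.roll(conv_lo[1::2], -1)


class TestComputeLeaders:
    def test_single_scale_neighbourhood_max(self):
        lead = compute_leaders(make_coeffs([[1.0, 3.0, 2.0, 5.0]]))
        np.testing.assert_array_equal(lead.L[0], [3, 3, 5, 5])

    def test_two_scales_sup_includes_finer_coefficients(self):
        lead = compute_leaders(make_coeffs([[1.0, 3.0, 2.0, 5.0],
                                            [4.0, 1.0]]))
        # L(2,0): own 4, finer {1,3,2,5} under 3-lambda, neighbour M(2,1)
        np.testing.assert_array_equal(lead.L[1], [5, 5])

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(5):
            arrays = [rng.uniform(0, 1, 16 // 2 ** (j - 1)) for j in (1, 2, 3, 4)]
            got = compute_leaders(make_coeffs(arrays)).L
            want = leaders_oracle(arrays)
            for g, w in zip(got, want):
                np.testing.assert_allclose(g, w)

    def test_leaders_dominate_coefficients(self):
        x = fbm(4096, 0.6, seed=1).values
        c = dwt_l1(x)
        lead = compute_leaders(c)
        for d, L in zip(c.d, lead.L):
            assert np.all(L >= d - 1e-15)


class TestStructureFunctions:
    def test_constant_leaders(self):
        lead = Leaders(L=[np.full(4, 2.0)], nj=np.array([4]))
        sf = structure_functions(lead, np.array([2.0]))
        assert sf.S[0, 0] == pytest.approx(4.0)

    def test_zeroth_moment_is_one(self):
        lead = compute_leaders(dwt_l1(fbm(2048, 0.4, seed=2).values))
        sf = structure_functions(lead, np.array([0.0]))
        np.testing.assert_allclose(sf.S[:, 0], 1.0)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(5)
        L = [rng.uniform(0.1, 2.0, 32), rng.uniform(0.1, 2.0, 16)]
        lead = Leaders(L=L, nj=np.array([32, 16]))
        q = np.array([-2.0, 0.5, 3.0])
        sf = structure_functions(lead, q)
        for j, arr in enumerate(L):
            for iq, qq in enumerate(q):
                assert sf.S[j, iq] == pytest.approx(
                    sum(v ** qq for v in arr) / len(arr))


class TestScalingFunction:
    def synthetic_leaders(self, H=0.7, j2=8, n0=512):
        return Leaders(L=[np.full(n0 // 2 ** (j - 1), 2.0 ** (j * H))
                          for j in range(1, j2 + 1)],
                       nj=np.array([n0 // 2 ** (j - 1) for j in range(1, j2 + 1)]))

    def test_exact_power_law_leaders(self):
        H = 0.7
        q = default_q_grid(5, 0.25)
        sf = structure_functions(self.synthetic_leaders(H), q)
        zeta, resid = scaling_function(sf, 1, 8)
        np.testing.assert_allclose(zeta, q * H, atol=1e-10)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_zeta_at_zero_vanishes(self):
        lead = compute_leaders(dwt_l1(fbm(4096, 0.3, seed=3).values))
        sf = structure_functions(lead, default_q_grid())
        zeta, _ = scaling_function(sf, 1, 7)
        assert abs(zeta[np.isclose(sf.q_grid, 0.0)][0]) < 1e-10

    def test_needs_three_scales(self):
        sf = structure_functions(self.synthetic_leaders(j2=4),
                                 np.array([1.0]))
        with pytest.raises(ValueError):
            scaling_function(sf, 1, 2)


class TestLegendreSpectrum:
    def test_linear_zeta_is_monofractal(self):
        q = default_q_grid(5, 0.25)
        alpha, f = legendre_spectrum(q * 0.7, q)
        np.testing.assert_allclose(alpha, 0.7, atol=1e-12)
        np.testing.assert_allclose(f, 1.0, atol=1e-12)

    def test_quadratic_zeta_closed_form(self):
        q = default_q_grid(5, 0.25)
        H, c = 0.7, 0.05
        alpha, f = legendre_spectrum(H * q - c * q ** 2 / 2.0, q)
        np.testing.assert_allclose(alpha, H - c * q, atol=1e-10)
        np.testing.assert_allclose(f, 1.0 - (H - alpha) ** 2 / (2 * c),
                                   atol=1e-10)

    def test_rejects_nonuniform_grid(self):
        q = np.array([-1.0, 0.0, 0.5, 3.0])
        with pytest.raises(ValueError):
            legendre_spectrum(q * 0.5, q)


class TestDirectSpectrum:
    def test_uniform_leaders_pin_monofractal_point(self):
        H, j2, n0 = 0.6, 8, 512
        lead = Leaders(L=[np.full(n0 // 2 ** (j - 1), 2.0 ** (j * H))
                          for j in range(1, j2 + 1)],
                       nj=np.array([n0 // 2 ** (j - 1)
                                    for j in range(1, j2 + 1)]))
        q = default_q_grid(2, 0.5)
        alpha, f = direct_spectrum(lead, q, 1, j2)
        np.testing.assert_allclose(alpha, H, atol=1e-10)
        np.testing.assert_allclose(f, 1.0, atol=1e-10)

    def test_agrees_with_legendre_on_cascade(self):
        sig = binomial_cascade(12, 0.7, seed=21)
        spec = multifractal_spectrum(sig.values, j1=1)
        lead = compute_leaders(dwt_l1(sig.values))
        alpha_d, f_d = direct_spectrum(lead, spec.q_grid, 1, spec.j2)
        assert np.abs(alpha_d - spec.alpha).max() < 0.07
        assert np.abs(f_d - spec.f).max() < 0.07


class TestSpectrumFeatures:
    def test_linear_zeta_has_zero_width(self):
        q = default_q_grid(5, 0.25)
        alpha, _ = legendre_spectrum(q * 0.7, q)
        a_min, a_0, a_max, d_alpha = spectrum_features(alpha, q, 5.0)
        assert (a_min, a_0, a_max) == pytest.approx((0.7, 0.7, 0.7))
        assert d_alpha == pytest.approx(0.0, abs=1e-12)

    def test_ordering_on_quadratic_zeta(self):
        q = default_q_grid(5, 0.25)
        alpha, _ = legendre_spectrum(0.7 * q - 0.02 * q ** 2, q)
        a_min, a_0, a_max, d_alpha = spectrum_features(alpha, q, 5.0)
        assert a_min < a_0 < a_max
        assert d_alpha == pytest.approx(a_max - a_min)

    def test_missing_grid_point_rejected(self):
        q = np.arange(0.25, 5.25, 0.25)  # no q=0, no -qmax
        with pytest.raises(ValueError):
            spectrum_features(np.ones_like(q), q, 5.0)


class TestHoelderBounds:
    def test_exact_power_law_coefficients(self):
        H = 0.7
        c = make_coeffs([np.full(512 // 2 ** (j - 1), 2.0 ** (j * H))
                         for j in range(1, 9)])
        hmin, hmax = hoelder_bounds(c, 1, 8)
        assert hmin == pytest.approx(H, abs=1e-10)
        assert hmax == pytest.approx(H, abs=1e-10)

    def test_all_zero_scales_rejected(self):
        c = make_coeffs([np.zeros(8), np.zeros(4), np.zeros(2)])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                hoelder_bounds(c, 1, 3)


class TestWaveletAdequacy:
    @pytest.mark.parametrize("hmax,nv,reg,expected", [
        (2.5, 3, 3.0, True),
        (3.2, 3, 3.0, False),
        (3.0, 3, 3.0, False),  # strict inequality at the boundary
    ])
    def test_condition(self, hmax, nv, reg, expected):
        report = check_wavelet_adequacy(0.5, hmax, nv, reg)
        assert report["pass"] is expected


class TestCascadeRecovery:
    def test_zeta_error_shrinks_with_depth(self):
        """Finite-resolution bias of the leaders estimate decreases as the
        cascade is refined (roughly halving from J=10 to J=14)."""
        q = default_q_grid(5, 0.25)
        mask = (q >= -2) & (q <= 5)
        true = cascade_zeta(0.6, q)
        errs = {}
        for J in (10, 14):
            sig = binomial_cascade(J, 0.6, seed=17)
            spec = multifractal_spectrum(sig.values, j1=1)
            errs[J] = np.abs(spec.zeta - true)[mask].max()
        assert errs[14] < 0.7 * errs[10]

    def test_zeta_concave_within_fit_noise(self):
        sig = binomial_cascade(14, 0.6, seed=11)
        spec = multifractal_spectrum(sig.values, j1=1)
        assert np.diff(spec.zeta, 2).max() <= 0.02
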