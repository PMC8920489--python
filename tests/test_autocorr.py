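"""Autocorrelation time, effective DOF, and the three variance estimators."""

import numpy as np
import pytest

import oisconn as oc
from oisconn.stats import default_max_lag, tukey_weights

from conftest import make_normalized


def bruteforce_autocorr(x, max_lag):
    """Direct O(T*M) biased sample autocorrelation (oracle for the FFT path)."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    c0 = (xc ** 2).sum() / x.size
    out = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        out[k] = (xc[:x.size - k] * xc[k:]).sum() / x.size / c0
    return out


class TestTaperedAutocorr:
    def test_fft_matches_bruteforce(self, rng):
        x = rng.standard_normal(400)
        np.testing.assert_allclose(oc.sample_autocorr(x, 50),
                                   bruteforce_autocorr(x, 50), atol=1e-10)

    def test_taper_endpoints(self, rng):
        w = tukey_weights(20)
        assert w[0] == 1.0 and w[20] == pytest.approx(0.0, abs=1e-15)
        rho = oc.tapered_autocorr(rng.standard_normal(300), 20)
        assert rho[0] == pytest.approx(1.0)
        assert rho[20] == pytest.approx(0.0, abs=1e-12)

    def test_ar1_lag1_matches_phi_times_weight(self):
        x = oc.generate_ar1_panel(1, 10_000, 0.6, seed=1)[0]
        M = default_max_lag(10_000)
        rho = oc.tapered_autocorr(x, M)
        assert abs(rho[1] - 0.6 * tukey_weights(M)[1]) < 0.02

    def test_max_lag_must_be_below_length(self, rng):
        with pytest.raises(ValueError, match="max_lag"):
            oc.tapered_autocorr(rng.standard_normal(50), 50)


class TestAutocorrTime:
    def test_white_noise_tau_approaches_one(self):
        panel = oc.generate_ar1_panel(200, 10_000, 0.0, seed=2)
        tau = oc.autocorr_time(panel, 200)
        assert 1.0 <= tau.mean() <= 1.05

    def test_ar1_tau_matches_geometric_series(self):
        panel = oc.generate_ar1_panel(200, 1000, 0.5, seed=3)
        tau = oc.autocorr_time(panel, default_max_lag(1000))
        assert abs(tau.mean() - 4.0 / 3.0) < 0.1 * 4.0 / 3.0

    def test_periodic_series_gives_long_tau(self):
        T, M = 1000, default_max_lag(1000)
        x = np.cos(2 * np.pi * np.arange(T) / 20.0)
        tau = oc.autocorr_time(x, M)
        # brute-force oracle: same sum evaluated from the direct estimate
        oracle = ((bruteforce_autocorr(x, M) * tukey_weights(M)) ** 2).sum()
        assert tau == pytest.approx(oracle, abs=1e-10)
        assert tau > 10.0  # long-tail regime, far from the white-noise value

    def test_two_sided_convention(self, rng):
        x = rng.standard_normal(500)
        one = oc.autocorr_time(x, 40)
        assert oc.autocorr_time(x, 40, two_sided=True) == pytest.approx(
            2 * one - 1)


class TestAutocorrMap:
    def test_homogeneous_panel_dispersion(self):
        series = make_normalized(oc.generate_ar1_panel(250, 300, 0.75, seed=4))
        am = oc.autocorr_map(series)
        assert am.tau.std() / am.tau.mean() < 0.15
        assert am.mean_tau == pytest.approx(am.tau.mean())

    def test_mixed_phi_ranking(self, rng):
        phi = rng.uniform(0.1, 0.9, 120)
        series = make_normalized(
            oc.generate_ar1_panel(120, 2000, phi, seed=5))
        am = oc.autocorr_map(series)
        from scipy.stats import spearmanr
        rank_r = spearmanr(am.tau, 1.0 / (1.0 - phi ** 2)).statistic
        assert rank_r > 0.9

    def test_tau_floor_at_one(self, rng):
        series = make_normalized(rng.standard_normal((30, 100)))
        assert np.all(oc.autocorr_map(series).tau >= 1.0)


class TestBartlettEdof:
    def test_arithmetic(self):
        am = oc.AutocorrMap(tau=np.full(50, 3.0), taper_max_lag=30,
                            mean_tau=3.0, T=300)
        assert oc.bartlett_edof(am).T_hat == pytest.approx(100.0)

    def test_white_noise_limit(self):
        series = make_normalized(oc.generate_ar1_panel(100, 2000, 0.0, seed=6))
        edof = oc.bartlett_edof(oc.autocorr_map(series))
        assert edof.T_hat == pytest.approx(2000, rel=0.05)

    def test_reported_edof_arises_from_global_mean_tau(self):
        # T=300 with a mask-average tau of 6.652 gives 45.1 effective DOF
        am = oc.AutocorrMap(tau=np.full(10, 6.652), taper_max_lag=35,
                            mean_tau=6.652, T=300)
        assert oc.bartlett_edof(am).T_hat == pytest.approx(45.1, abs=0.05)

    def test_median_summary_option(self):
        tau = np.array([1.0, 1.0, 1.0, 9.0])
        am = oc.AutocorrMap(tau=tau, taper_max_lag=10, mean_tau=3.0, T=300)
        assert oc.bartlett_edof(am, summary="mean").T_hat == pytest.approx(100)
        assert oc.bartlett_edof(am, summary="median").T_hat == pytest.approx(300)


class TestVarianceFormulas:
    def test_naive_arithmetic(self):
        assert oc.variance_naive(0.0, 103) == pytest.approx(0.01)
        assert oc.variance_naive(1.0, 103) == 0.0
        assert oc.variance_naive(0.5, 53) == pytest.approx(0.75 ** 2 / 50)

    def test_bartlett_arithmetic(self):
        edof = oc.EffectiveDof(T_hat=100.0, T=300, mean_tau=3.0)
        assert oc.variance_bartlett(0.0, edof) == pytest.approx(0.01)
        e451 = oc.EffectiveDof(T_hat=45.1, T=300, mean_tau=300 / 45.1)
        # (1 - 0.5^2)^2 = 0.5625, divided by the effective DOF
        assert oc.variance_bartlett(0.5, e451) == pytest.approx(0.5625 / 45.1)

    def test_bartlett_reduces_to_naive_for_white_noise(self):
        T = 300
        edof = oc.EffectiveDof(T_hat=float(T), T=T, mean_tau=1.0)
        v_b = oc.variance_bartlett(0.3, edof)
        v_n = oc.variance_naive(0.3, T)
        assert v_b / v_n == pytest.approx((T - 3) / T)


class TestXdfVariance:
    def test_white_noise_pair_floors_at_naive(self):
        # plug-zero evaluation of the xDF equation gives (T-2)/T^2, which is
        # below the naive floor 1/(T-3) for every T > 3, so white pairs floor
        T = 300
        x = oc.generate_ar1_panel(200, T, 0.0, seed=7)
        y = oc.generate_ar1_panel(200, T, 0.0, seed=8)
        v, flag = oc.variance_xdf_pairs(x, y)
        assert (T - 2) / T ** 2 < 1.0 / (T - 3)
        assert flag.mean() > 0.5
        r0 = [float(np.corrcoef(a, b)[0, 1]) for a, b in zip(x, y)]
        floor = oc.variance_naive(np.asarray(r0), T)
        np.testing.assert_allclose(v[flag], floor[flag], rtol=1e-10)
        assert np.all(v >= floor - 1e-15)

    def test_autocorrelated_pair_exceeds_naive(self):
        T = 300
        x = oc.generate_ar1_panel(300, T, 0.8, seed=9)
        y = oc.generate_ar1_panel(300, T, 0.8, seed=10)
        v, flag = oc.variance_xdf_pairs(x, y)
        assert v.mean() / (1.0 / (T - 3)) > 1.5
        assert flag.mean() < 0.1

    def test_degenerate_self_pair_finite_and_flagged(self):
        x = oc.generate_ar1_panel(1, 300, 0.5, seed=11)[0]
        v, flag = oc.variance_xdf(x, x)
        assert np.isfinite(v) and v > 0
        assert flag  # (1-R0^2) terms vanish; clipped naive floor applies

    def test_matrix_version_matches_pairwise(self):
        series = make_normalized(oc.generate_ar1_panel(12, 200, 0.6, seed=12))
        vm = oc.variance_xdf_matrix(series, chunk=5)
        i, j = 7, 2
        v, _ = oc.variance_xdf(series.data[i], series.data[j])
        assert vm.V[i, j] == pytest.approx(v, rel=1e-10)
        np.testing.assert_allclose(vm.V, vm.V.T)

    def test_cross_term_variant_agrees_at_null(self):
        x = oc.generate_ar1_panel(100, 300, 0.6, seed=13)
        y = oc.generate_ar1_panel(100, 300, 0.6, seed=14)
        v1, _ = oc.variance_xdf_pairs(x, y, cross_term="squares_product")
        v2, _ = oc.variance_xdf_pairs(x, y, cross_term="lag_product")
        # the R0^2-weighted term is negligible for null pairs
        np.testing.assert_allclose(v1, v2, rtol=0.02)


class TestZScoresAndPvalues:
    def test_naive_reduction(self):
        T, r = 103, 0.5
        z = oc.zscore(oc.fisher_transform(r), r, oc.variance_naive(r, T))
        assert z == pytest.approx(np.sqrt(T - 3) * np.arctanh(r), rel=1e-12)
        assert z == pytest.approx(5.49306, abs=1e-4)
        assert oc.zscore(0.0, 0.0, 0.01) == 0.0

    def test_bartlett_is_uniform_z_shrinkage(self, ar1_series):
        sn = oc.correlation_stats(ar1_series, "naive")
        sb = oc.correlation_stats(ar1_series, "bartlett")
        T = ar1_series.n_frames
        T_hat = sb.variance.edof.T_hat
        il = np.tril_indices(sn.Z.shape[0], -1)
        ratio = sb.Z[il] / sn.Z[il]
        np.testing.assert_allclose(ratio, np.sqrt(T_hat / (T - 3)),
                                   rtol=1e-10)

    def test_xdf_z_never_exceeds_naive(self, ar1_series):
        sn = oc.correlation_stats(ar1_series, "naive")
        sx = oc.correlation_stats(ar1_series, "xdf")
        il = np.tril_indices(sn.Z.shape[0], -1)
        assert np.all(np.abs(sx.Z[il]) <= np.abs(sn.Z[il]) + 1e-12)

    def test_pvalue_reference_points(self):
        assert oc.pvalue(0.0) == pytest.approx(1.0)
        assert oc.pvalue(1.959964) == pytest.approx(0.05, abs=1e-6)
        assert oc.pvalue(3.0) < oc.pvalue(2.0) < oc.pvalue(1.0)
        assert oc.pvalue(50.0) > 0  # underflow clamped


class TestKsNormality:
    def test_standard_normal_sample(self, rng):
        assert oc.ks_normality(rng.standard_normal(100_000)) < 0.01

    def test_shifted_sample_distance(self, rng):
        # sup_x |Phi(x) - Phi(x-1)| = Phi(0.5) - Phi(-0.5) = 0.3829
        ks = oc.ks_normality(rng.standard_normal(100_000) + 1.0)
        assert ks == pytest.approx(0.3829, abs=0.01)

    def test_minimum_sample_size(self, rng):
        with pytest.raises(ValueError, match="50"):
            oc.ks_normality(rng.standard_normal(10))


class TestParcelLengthRegression:
    @staticmethod
    def acmap(tau):
        tau = np.asarray(tau, dtype=float)
        return oc.AutocorrMap(tau=tau, taper_max_lag=10,
                              mean_tau=float(tau.mean()), T=300)

    @staticmethod
    def parcellation(areas):
        side = int(np.ceil(np.sqrt(sum(areas))))
        img = np.zeros((side, side), dtype=bool)
        img.flat[:sum(areas)] = True
        mask = oc.BrainMask.from_image(img)
        groups = np.repeat(np.arange(1, len(areas) + 1), areas)
        labels = np.zeros(mask.shape, dtype=int)
        labels[mask.pixel_index[:, 0], mask.pixel_index[:, 1]] = groups
        return oc.Parcellation.from_labels(labels, mask)

    def test_constant_tau_zero_slope(self):
        parc = self.parcellation([4, 9, 16])
        slope, r = oc.parcel_length_regression(self.acmap([2, 2, 2]), parc)
        assert slope == 0.0

    def test_exact_linear_recovery(self):
        parc = self.parcellation([4, 9, 16, 25])
        lengths = np.sqrt(parc.areas)
        tau = 5.0 - 0.5 * lengths
        slope, r = oc.parcel_length_regression(self.acmap(tau), parc)
        assert slope == pytest.approx(-0.5, abs=1e-12)
        assert abs(r) == pytest.approx(1.0, abs=1e-12)

    def test_tau_decreasing_in_parcel_size_gives_negative_slope(self):
        # emulate lower autocorrelation in larger parcels via per-parcel phi
        areas = [4, 9, 16, 25, 36]
        parc = self.parcellation(areas)
        phi_by_parcel = np.array([0.85, 0.8, 0.7, 0.6, 0.5])
        phi = np.repeat(phi_by_parcel, areas)
        panel = oc.generate_ar1_panel(sum(areas), 2000, phi, seed=15)
        series = make_normalized(panel)
        tau = np.array([oc.autocorr_time(
            panel[parc.member_rows(series.mask, int(pid))].mean(axis=0), 60)
            for pid in parc.parcel_ids])
        slope, r = oc.parcel_length_regression(self.acmap(tau), parc)
        assert slope < 0
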