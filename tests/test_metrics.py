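"""Participation ratio, sampling predictions, collapse index, alpha fit."""

import numpy as np
import pytest

import ermspec as es
from ermspec.metrics import (collapse_index_from_spectra, covariance_moments,
                             dpr_formula, fsap_mu_over_d)
from ermspec.sampling import SamplingResult


class TestDpr:
    @pytest.mark.parametrize("lam", [[7.0, 7.0, 1.0], [9.0, 3.0, 3.0]])
    def test_worked_example(self, lam):
        """Two different spectra with the same effective dimensionality."""
        assert es.dpr(lam) == pytest.approx(25.0 / 11.0)

    def test_equal_eigenvalues_give_N(self):
        assert es.dpr(np.full(37, 2.5)) == pytest.approx(37.0)

    def test_scale_invariance(self):
        lam = np.array([5.0, 1.0, 0.25])
        assert es.dpr(lam) == pytest.approx(es.dpr(100 * lam))

    def test_bounds(self):
        rng = np.random.default_rng(0)
        lam = rng.uniform(0, 1, 50)
        assert 1.0 <= es.dpr(lam) <= 50.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            es.dpr(np.zeros(4))


class TestDprLimit:
    def test_arithmetic(self):
        assert es.dpr_limit(1.0, 0.01) == pytest.approx(100.0)

    def test_diagonal_gives_infinity(self):
        assert es.dpr_limit(1.0, 0.0) == np.inf

    def test_moment_plugin_matches_spectrum(self, tpdf_kernel):
        """Plug-in limit vs direct D_PR of a large simulated ERM."""
        space = es.FunctionalSpace(d=2, L=10.0, N=2048)  # N >> D_PR
        erm = es.make_erm(space, tpdf_kernel, seed=11)
        e2, e4, m2 = covariance_moments(erm.C)
        lam = np.clip(np.linalg.eigvalsh(erm.C), 0, None)
        assert es.dpr_limit(e2, m2) == pytest.approx(es.dpr(lam), rel=0.10)


class TestDprCurve:
    def test_limit_equals_dpr_limit(self, small_erm):
        e2, e4, m2 = covariance_moments(small_erm.C)
        big = es.dpr_curve_pred(small_erm.C, [10**9])[0]
        assert big == pytest.approx(es.dpr_limit(e2, m2), rel=1e-3)

    def test_monotone_nondecreasing(self, small_erm):
        curve = es.dpr_curve_pred(small_erm.C, [2, 8, 32, 128, 512])
        assert np.all(np.diff(curve) >= 0)

    def test_small_N_rejected(self, small_erm):
        with pytest.raises(ValueError):
            es.dpr_curve_pred(small_erm.C, [1, 4])

    def test_predicts_measured_subsample_dimensionality(self, default_erm):
        """Moment prediction vs D_PR measured on random subsets."""
        C = default_erm.C
        rng = np.random.default_rng(1)
        for N in (64, 128, 256, 512):
            vals = []
            for _ in range(8):
                idx = rng.choice(1024, N, replace=False)
                lam = np.clip(np.linalg.eigvalsh(C[np.ix_(idx, idx)]), 0, None)
                vals.append(es.dpr(lam))
            pred = es.dpr_curve_pred(C, [N])[0]
            assert abs(pred - np.mean(vals)) < max(2 * np.std(vals), 0.15 * pred)


class TestSamplingPrediction:
    MOMENTS = (1.0, 1.8, 0.02)

    def test_zero_anatomical_correlation_reduces_to_random(self):
        a = es.dpr_sampling_pred("asap", 0.5, self.MOMENTS, 1024,
                                 mu_over_d=0.25, R_ASap=0.0)
        r = es.dpr_sampling_pred("rsap", 0.5, self.MOMENTS, 1024)
        assert a.predicted == pytest.approx(r.predicted)

    def test_full_anatomical_correlation_reduces_to_functional(self):
        a = es.dpr_sampling_pred("asap", 0.5, self.MOMENTS, 1024,
                                 mu_over_d=0.25, R_ASap=1.0)
        f = es.dpr_sampling_pred("fsap", 0.5, self.MOMENTS, 1024,
                                 mu_over_d=0.25)
        assert a.predicted == pytest.approx(f.predicted)
        assert a.k_f == pytest.approx(0.5)

    def test_full_sampling_fraction_schemes_coincide(self):
        preds = [es.dpr_sampling_pred(s, 1.0, self.MOMENTS, 1024,
                                      mu_over_d=0.25, R_ASap=0.4).predicted
                 for s in ("rsap", "asap", "fsap")]
        assert preds[0] == pytest.approx(preds[1])
        assert preds[0] == pytest.approx(preds[2])

    def test_ordering_rsap_asap_fsap(self):
        r = es.dpr_sampling_pred("rsap", 0.25, self.MOMENTS, 1024)
        a = es.dpr_sampling_pred("asap", 0.25, self.MOMENTS, 1024,
                                 mu_over_d=0.25, R_ASap=0.33)
        f = es.dpr_sampling_pred("fsap", 0.25, self.MOMENTS, 1024,
                                 mu_over_d=0.25)
        assert r.predicted >= a.predicted >= f.predicted

    def test_rsap_saturates_fsap_scales(self):
        """RSap dimensionality is k-independent at large N; FSap follows
        the k^(2 mu/d) scaling."""
        ks = np.array([0.125, 0.25, 0.5, 1.0])
        r = [es.dpr_sampling_pred("rsap", k, self.MOMENTS, 2**16).predicted
             for k in ks]
        assert np.ptp(r) / r[-1] < 0.01
        f = [es.dpr_sampling_pred("fsap", k, self.MOMENTS, 2**16,
                                  mu_over_d=0.25).predicted for k in ks]
        slope = np.polyfit(np.log(ks), np.log(f), 1)[0]
        assert slope == pytest.approx(2 * 0.25, abs=0.02)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            es.dpr_sampling_pred("rsap", 0.0, self.MOMENTS, 1024)
        with pytest.raises(ValueError):
            es.dpr_sampling_pred("asap", 0.5, self.MOMENTS, 1024,
                                 mu_over_d=0.25, R_ASap=1.5)


class TestCollapseIndex:
    def test_identical_curves_give_zero(self):
        """Spectra lying on the same log-log line collapse exactly."""
        N0, Ns = 512, 256
        lam_full = (np.arange(1, N0 + 1) / N0) ** -0.6
        lam_half = (np.arange(1, Ns + 1) / Ns) ** -0.6
        ci, q0, q1 = collapse_index_from_spectra(lam_full, lam_half)
        assert ci == pytest.approx(0.0, abs=1e-12)

    def test_pure_shift_recovered(self):
        """A uniform vertical shift of 2^s maps to CI = s."""
        N0, Ns = 512, 256
        lam_full = (np.arange(1, N0 + 1) / N0) ** -0.6
        lam_half = 2.0 ** 0.3 * (np.arange(1, Ns + 1) / Ns) ** -0.6
        ci, _, _ = collapse_index_from_spectra(lam_full, lam_half)
        assert ci == pytest.approx(0.3, rel=1e-6)

    def test_never_crossing_one_rejected(self):
        lam_full = np.full(64, 10.0)
        lam_half = np.full(32, 10.0)
        with pytest.raises(ValueError):
            collapse_index_from_spectra(lam_full, lam_half)

    def test_mu_over_d_ordering(self):
        """Slower correlation decay relative to dimension means a more
        scale-invariant ERM spectrum."""
        kA = es.KernelSpec("tpdf", mu=0.5, epsilon=0.03125)
        kB = es.KernelSpec("tpdf", mu=1.3, epsilon=0.03125)
        spA = es.FunctionalSpace.from_density(d=3, N=1024, rho=256.0)
        spB = es.FunctionalSpace.from_density(d=1, N=1024, rho=256.0)
        ciA = es.collapse_index(es.make_erm(spA, kA, seed=0).C,
                                n_repeats=10, seed=1)
        ciB = es.collapse_index(es.make_erm(spB, kB, seed=0).C,
                                n_repeats=10, seed=1)
        assert ciA.value < ciB.value

    def test_odd_size_rejected(self):
        with pytest.raises(ValueError):
            es.collapse_index(np.eye(7))


class TestCollapseIndexTheory:
    def test_matches_simulation(self, tpdf_kernel):
        """Theory CI vs half-sampling CI of simulated ERMs (lognormal
        variances, rho=10.24)."""
        space = es.FunctionalSpace(d=2, L=10.0, N=1024)
        vm = es.VarianceModel(kind="lognormal", location=-0.125, scale=0.5)
        cis = [es.collapse_index(es.make_erm(space, tpdf_kernel, vm, seed=s).C,
                                 n_repeats=10, seed=s).value for s in range(4)]
        sim = float(np.mean(cis))
        th = es.collapse_index_theory(tpdf_kernel, space, vm).value
        assert th == pytest.approx(sim, rel=0.20)

    def test_heterogeneous_variances_improve_collapse(self, tpdf_kernel):
        """CI decreases as E(sigma^4) grows at fixed E(sigma^2)=1."""
        space = es.FunctionalSpace(d=2, L=10.0, N=1024)
        values = []
        for scale in (1e-6, 0.5, 1.0):
            vm = es.VarianceModel(kind="lognormal",
                                  location=-scale**2 / 2, scale=scale)
            values.append(es.collapse_index_theory(tpdf_kernel, space, vm).value)
        assert values[0] > values[1] > values[2]

    def test_small_mu_over_d_nearly_invariant(self):
        """mu/d -> 0 at high density: theory CI below 0.1."""
        kern = es.KernelSpec("tpdf", mu=0.5, epsilon=0.03125)
        space = es.FunctionalSpace.from_density(d=3, N=1024, rho=256.0)
        ci = es.collapse_index_theory(kern, space)
        assert ci.value < 0.1


class TestAlphaFit:
    @staticmethod
    def _power_law_result(alpha, sizes=(512, 256, 128, 64)):
        levels = [(N, (np.arange(1, N + 1) / N) ** -alpha) for N in sizes]
        return SamplingResult(scheme="RSap", levels=levels,
                              block_assignments=[])

    def test_exact_power_law_recovered(self):
        a, r2 = es.alpha_fit(self._power_law_result(0.75))
        assert a == pytest.approx(0.75, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_requires_four_levels(self):
        res = self._power_law_result(0.5, sizes=(128, 64))
        with pytest.raises(ValueError):
            es.alpha_fit(res)

    def test_wishart_fits_worse_than_erm(self, tpdf_kernel):
        """No single power law for the Marchenko-Pastur spectrum."""
        C_w = es.wishart_cov(512, 1024, seed=0)
        res_w = es.rsap(C_w, 3, seed=1)
        _, r2_w = es.alpha_fit(res_w)
        space = es.FunctionalSpace(d=2, L=7.0, N=512)
        C_e = es.make_erm(space, tpdf_kernel, seed=2).C
        res_e = es.rsap(C_e, 3, seed=1)
        _, r2_e = es.alpha_fit(res_e)
        assert r2_e > r2_w

    def test_matches_direct_slope_of_full_spectrum(self, default_erm):
        """Pooled multi-level fit agrees with a single-level log-log fit."""
        C = es.trace_normalized(default_erm.C)
        res = es.rsap(C, 3, seed=0)
        a, r2 = es.alpha_fit(res)
        lam = np.sort(np.linalg.eigvalsh(C))[::-1]
        r = np.arange(5, 103)
        direct = -np.polyfit(np.log(r / 1024), np.log(lam[r - 1]), 1)[0]
        assert a == pytest.approx(direct, rel=0.15)
        assert r2 > 0.95


def test_fsap_mu_over_d_recovers_kernel_exponent(default_erm, tpdf_kernel):
    """Slope of log E^k(C^2) vs log k across FSap levels estimates mu/d."""
    est = fsap_mu_over_d(default_erm.C, n_levels=3)
    assert est == pytest.approx(0.25, abs=0.10)


def test_moment_form_equals_spectral_form(small_erm):
    lam = np.clip(np.linalg.eigvalsh(small_erm.C), 0, None)
    e2, e4, m2 = covariance_moments(small_erm.C)
    assert dpr_formula(256, e2, e4, m2) == pytest.approx(es.dpr(lam), rel=1e-6)
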