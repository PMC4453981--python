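"""Debye curves, smearing, Guinier fits and R-factor comparison."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from beadsas import scattering_curve as sc
from beadsas.datatypes import ScatterCurve, SmearingSpec, SphereModel


def exact_debye(centres, r, q):
    """O(n^2) all-pairs Debye oracle (no histogram)."""
    n = len(centres)
    d = pdist(centres)
    interference = np.sum(np.sinc(np.outer(q, d) / np.pi), axis=1)
    return sc.squared_form_factor(q, r) * (1 / n + 2 / n ** 2 * interference)


def grid_scan_rfactor(i_expt, i_theo):
    """Dense eta-grid oracle for the R-factor minimum."""
    a, b = np.abs(i_expt), np.abs(i_theo)
    denom = a.sum()
    coarse = np.geomspace(1e-3, 1e3, 2001)
    r_coarse = 100 * np.abs(a[None, :] - coarse[:, None] * b).sum(1) / denom
    centre = coarse[np.argmin(r_coarse)]
    fine = np.linspace(0.99 * centre, 1.01 * centre, 20001)
    r_fine = 100 * np.abs(a[None, :] - fine[:, None] * b).sum(1) / denom
    k = np.argmin(r_fine)
    return r_fine[k], fine[k], r_coarse


class TestDistanceHistogram:
    def test_two_spheres_single_occupied_bin(self):
        model = SphereModel(np.array([[0, 0, 0], [0, 0, 1.0]]), 0.5)
        hist = sc.distance_histogram(model, "modern", nbins=10)
        assert hist.counts.sum() == 1
        assert np.count_nonzero(hist.counts) == 1

    def test_collinear_equidistant_counts(self):
        s = 0.7
        model = SphereModel(np.array([[0, 0, i * s] for i in range(4)]), 0.5)
        hist = sc.distance_histogram(model, "modern", nbins=3)
        # pair distances {s, 2s, 3s} with multiplicities {3, 2, 1}
        np.testing.assert_array_equal(hist.counts, [3, 2, 1])
        np.testing.assert_allclose(
            hist.bin_centres, [s + s / 3, 2 * s, 3 * s - s / 3])

    def test_classic_defaults_to_400_bins(self):
        model = SphereModel(np.random.default_rng(3).uniform(0, 2, (30, 3)),
                            0.5)
        hist = sc.distance_histogram(model, "classic", bin_width=0.01)
        assert hist.nbins == sc.CLASSIC_NBINS == 400
        assert hist.counts.sum() == 30 * 29 // 2

    def test_classic_requires_bin_width(self):
        model = SphereModel(np.zeros((2, 3)) + [[0, 0, 0], [0, 0, 1]], 0.5)
        with pytest.raises(ValueError, match="bin_width"):
            sc.distance_histogram(model, "classic")

    def test_classic_overflow_is_an_error(self):
        model = SphereModel(np.array([[0, 0, 0], [0, 0, 9.0]]), 0.5)
        with pytest.raises(ValueError, match="exceed"):
            sc.distance_histogram(model, "classic", bin_width=0.01)

    def test_counts_sum_to_pair_count(self, rng):
        for n in (2, 17, 120):
            model = SphereModel(rng.uniform(0, 4, (n, 3)), 0.5)
            hist = sc.distance_histogram(model, "modern", nbins=50)
            assert hist.counts.sum() == n * (n - 1) // 2

    def test_single_sphere_rejected(self):
        with pytest.raises(ValueError):
            sc.distance_histogram(SphereModel(np.zeros((1, 3)), 0.5))


class TestSquaredFormFactor:
    def test_unity_at_zero(self):
        assert sc.squared_form_factor(0.0, 0.25) == pytest.approx(1.0)

    def test_first_zero_of_sphere_amplitude(self):
        # first root of tan x = x at x = 4.4934
        assert sc.squared_form_factor(4.4934 / 0.25, 0.25) < 1e-8

    def test_bounded_on_dense_sweep(self):
        q = np.linspace(0, 100, 20001)
        g = sc.squared_form_factor(q, 0.25)
        assert np.all(g >= 0) and np.all(g <= 1.0 + 1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            sc.squared_form_factor(-1.0, 0.25)
        with pytest.raises(ValueError):
            sc.squared_form_factor(1.0, -0.25)


class TestDebyeCurve:
    def test_unit_normalization_at_low_q(self, ball_model):
        hist = sc.distance_histogram(ball_model, "modern", nbins=500)
        curve = sc.debye_curve(hist, ball_model.radius, np.array([1e-6]))
        assert abs(curve.i[0] - 1.0) < 1e-6

    def test_two_sphere_closed_form(self):
        d, r = 1.3, 0.25
        model = SphereModel(np.array([[0, 0, 0], [0, 0, d]]), 2 * r)
        hist = sc.distance_histogram(model, "modern", nbins=1)
        q = sc.theoretical_q_grid(2.0, 50)
        curve = sc.debye_curve(hist, r, q)
        expected = sc.squared_form_factor(q, r) * 0.5 * (
            1 + np.sin(q * d) / (q * d))
        np.testing.assert_allclose(curve.i, expected, rtol=1e-10)

    def test_histogram_matches_allpairs_within_one_percent(self, rng):
        centres = rng.uniform(0, 5, (50, 3))
        model = SphereModel(centres, 0.5)
        hist = sc.distance_histogram(model, "modern", nbins=3000)
        q = sc.theoretical_q_grid(2.0, 100)
        curve = sc.debye_curve(hist, 0.25, q)
        exact = exact_debye(centres, 0.25, q)
        assert np.max(np.abs(curve.i - exact) / np.abs(exact)) < 0.01

    def test_invalid_radius(self, ball_model):
        hist = sc.distance_histogram(ball_model, "modern", nbins=100)
        with pytest.raises(ValueError):
            sc.debye_curve(hist, -0.1, np.array([0.1]))


class TestSmearing:
    @pytest.fixture
    def oscillatory_curve(self):
        q = np.linspace(0.01, 2.0, 400)
        return ScatterCurve(q=q, i=np.exp(-q) * (1 + 0.3 * np.cos(12 * q)))

    def test_zero_width_kernel_is_identity(self, oscillatory_curve):
        spec = SmearingSpec(wavelength=0.6, spread=0.0, divergence=0.0)
        smeared = sc.smear_curve(oscillatory_curve, spec)
        np.testing.assert_allclose(smeared.i, oscillatory_curve.i)
        assert smeared.smeared

    def test_constant_curve_preserved(self):
        q = np.linspace(0.01, 2.0, 300)
        curve = ScatterCurve(q=q, i=np.full_like(q, 4.2))
        spec = SmearingSpec(wavelength=0.6, spread=0.1, divergence=0.01)
        smeared = sc.smear_curve(curve, spec)
        np.testing.assert_allclose(smeared.i, 4.2, rtol=1e-10)

    def test_gaussian_variance_additivity(self):
        # narrow peak of width s convolved with a near-constant sigma0
        q = np.linspace(0.0, 4.0, 2001)
        s, mu = 0.05, 2.0
        curve = ScatterCurve(q=q, i=np.exp(-0.5 * ((q - mu) / s) ** 2))
        sigma0 = 0.08
        spec = SmearingSpec(wavelength=0.6, spread=0.0,
                            divergence=sigma0 / ((4 * np.pi / 0.6)
                                                 / 2.3548200450309493))
        smeared = sc.smear_curve(curve, spec)
        weights = smeared.i / smeared.i.sum()
        mean = np.sum(weights * q)
        var = np.sum(weights * (q - mean) ** 2)
        assert var == pytest.approx(s ** 2 + sigma0 ** 2, rel=0.05)

    def test_feature_softening(self, oscillatory_curve):
        spec = SmearingSpec(wavelength=0.6, spread=0.05, divergence=0.01)
        smeared = sc.smear_curve(oscillatory_curve, spec)
        roughness = lambda i: np.max(np.abs(np.diff(i, 2)))
        assert roughness(smeared.i) < roughness(oscillatory_curve.i)

    def test_already_smeared_rejected(self, oscillatory_curve):
        spec = SmearingSpec(wavelength=0.6, spread=0.05, divergence=0.01)
        smeared = sc.smear_curve(oscillatory_curve, spec)
        with pytest.raises(ValueError, match="already"):
            sc.smear_curve(smeared, spec)

    def test_curve_shorter_than_kernel_rejected(self):
        q = np.linspace(0.01, 0.05, 5)
        curve = ScatterCurve(q=q, i=np.ones(5))
        spec = SmearingSpec(wavelength=0.6, spread=0.0, divergence=0.1)
        with pytest.raises(ValueError, match="kernel support"):
            sc.smear_curve(curve, spec)


class TestIncoherentBaseline:
    def test_zero_fraction_identity(self):
        curve = ScatterCurve(q=np.array([0.1, 0.2]), i=np.array([1.0, 0.5]))
        out = sc.apply_incoherent_baseline(curve, 0.0)
        np.testing.assert_allclose(out.i, curve.i)

    def test_flat_addition_on_normalized_curve(self):
        q = np.linspace(0.01, 2, 50)
        curve = ScatterCurve(q=q, i=np.exp(-q) / np.exp(-q[0]))
        out = sc.apply_incoherent_baseline(curve, 0.01)
        np.testing.assert_allclose(out.i - curve.i, 0.01)

    def test_negative_fraction_rejected(self):
        curve = ScatterCurve(q=np.array([0.1, 0.2]), i=np.array([1.0, 0.5]))
        with pytest.raises(ValueError):
            sc.apply_incoherent_baseline(curve, -0.01)

    def test_baseline_must_follow_fitting(self):
        """The flat correction is applied after curve fitting, so the
        R-factor refuses a baseline-corrected theoretical curve."""
        q = np.linspace(0.01, 2, 50)
        curve = ScatterCurve(q=q, i=np.exp(-q))
        expt = ScatterCurve(q=q, i=np.exp(-q), kind="experimental")
        corrected = sc.apply_incoherent_baseline(curve, 0.01)
        with pytest.raises(ValueError, match="after curve fitting"):
            sc.r_factor(corrected, expt, 0.1, 1.5)


class TestGuinierRg:
    def test_exact_recovery_on_synthetic_curve(self):
        rg, i0 = 3.0, 2.5
        q = np.linspace(0.05, 0.45, 60)
        curve = ScatterCurve(q=q, i=i0 * np.exp(-rg ** 2 * q ** 2 / 3))
        fit = sc.guinier_rg(curve, 0.17, 0.43)
        assert fit.value == pytest.approx(rg, rel=1e-6)
        assert fit.i0 == pytest.approx(i0, rel=1e-6)

    def test_dense_ball_debye_curve(self, ball_model):
        hist = sc.distance_histogram(ball_model, "modern", nbins=2000)
        q = sc.theoretical_q_grid(2.0, 400)
        curve = sc.debye_curve(hist, ball_model.radius, q)
        expected = np.sqrt(3 / 5) * 3.0
        # fit at the low end of the recommended Q*Rg band, where the
        # Guinier approximation of a globular body holds best
        fit = sc.guinier_rg(curve, 0.5 / expected, 0.9 / expected)
        assert fit.value == pytest.approx(expected, rel=0.03)

    def test_two_point_window_rejected(self):
        q = np.linspace(0.05, 0.45, 60)
        curve = ScatterCurve(q=q, i=np.exp(-q ** 2))
        with pytest.raises(ValueError, match="3 points"):
            sc.guinier_rg(curve, 0.05, 0.057)

    def test_positive_slope_rejected(self):
        q = np.linspace(0.05, 0.45, 60)
        curve = ScatterCurve(q=q, i=np.exp(+q ** 2))
        with pytest.raises(ValueError, match="slope"):
            sc.guinier_rg(curve, 0.1, 0.4)

    def test_qrg_band_warning(self):
        rg = 3.0
        q = np.linspace(0.05, 0.8, 100)
        curve = ScatterCurve(q=q, i=np.exp(-rg ** 2 * q ** 2 / 3))
        with pytest.warns(UserWarning, match="recommended"):
            sc.guinier_rg(curve, 0.5, 0.8)  # Q*Rg up to 2.4


class TestGuinierRxs:
    def test_exact_recovery_on_rod_curve(self):
        rxs = 1.5
        q = np.linspace(0.4, 0.9, 80)
        curve = ScatterCurve(q=q, i=2.0 * np.exp(-rxs ** 2 * q ** 2 / 2) / q)
        fit = sc.guinier_rxs(curve, 0.45, 0.85)
        assert fit.value == pytest.approx(rxs, rel=1e-6)

    def test_overlapping_rg_window_rejected(self):
        q = np.linspace(0.05, 0.9, 80)
        curve = ScatterCurve(q=q, i=np.exp(-q ** 2) / q)
        with pytest.raises(ValueError, match="overlap"):
            sc.guinier_rxs(curve, 0.3, 0.6, rg_window=(0.1, 0.35))

    def test_positive_slope_is_error_not_nan(self):
        q = np.linspace(0.4, 0.9, 50)
        curve = ScatterCurve(q=q, i=np.exp(q ** 2) / q)
        with pytest.raises(ValueError, match="slope"):
            sc.guinier_rxs(curve, 0.45, 0.85)


class TestMatchQGrid:
    def test_identical_grids_pair_one_to_one(self):
        q = np.linspace(0.1, 1.0, 10)
        theo = ScatterCurve(q=q, i=q * 2)
        expt = ScatterCurve(q=q, i=q * 3, kind="experimental")
        qe, ie, it = sc.match_q_grid(theo, expt, 0.0, 2.0)
        np.testing.assert_allclose(it, theo.i)
        assert len(qe) == 10

    def test_tie_breaks_toward_lower_q(self):
        theo = ScatterCurve(q=np.array([0.10, 0.20]), i=np.array([7.0, 9.0]))
        expt = ScatterCurve(q=np.array([0.15, 0.3]), i=np.array([1.0, 1.0]),
                            kind="experimental")
        _, _, it = sc.match_q_grid(theo, expt, 0.0, 1.0)
        assert it[0] == 7.0  # equidistant -> lower theoretical Q

    def test_matches_brute_force_nearest_neighbour(self, rng):
        qt = np.sort(rng.uniform(0, 2, 80))
        qt = np.unique(qt)
        qe = np.unique(np.sort(rng.uniform(0.1, 1.9, 60)))
        theo = ScatterCurve(q=qt, i=rng.uniform(1, 2, len(qt)))
        expt = ScatterCurve(q=qe, i=np.ones(len(qe)), kind="experimental")
        _, _, it = sc.match_q_grid(theo, expt, 0.0, 2.0)
        for qk, ik in zip(qe, it):
            dists = np.abs(qt - qk)
            best = np.flatnonzero(dists == dists.min())[0]  # lower-Q tie
            assert ik == theo.i[best]

    def test_empty_window_rejected(self):
        theo = ScatterCurve(q=np.array([0.1, 0.2]), i=np.array([1.0, 2.0]))
        expt = ScatterCurve(q=np.array([0.5, 0.9]), i=np.array([1.0, 1.0]),
                            kind="experimental")
        with pytest.raises(ValueError, match="no experimental points"):
            sc.match_q_grid(theo, expt, 0.0, 0.3)


class TestRFactor:
    @pytest.fixture
    def theoretical(self):
        q = np.linspace(0.02, 2.0, 150)
        return ScatterCurve(q=q, i=np.exp(-2 * q ** 2) + 0.01)

    def test_self_comparison_is_zero_with_unit_scale(self, theoretical):
        expt = ScatterCurve(q=theoretical.q, i=theoretical.i.copy(),
                            kind="experimental")
        result = sc.r_factor(theoretical, expt, 0.1, 1.8)
        assert result.r_factor == pytest.approx(0.0, abs=1e-12)
        assert result.eta == pytest.approx(1.0)

    def test_pure_scale_recovered(self, theoretical):
        expt = ScatterCurve(q=theoretical.q, i=2.0 * theoretical.i,
                            kind="experimental")
        result = sc.r_factor(theoretical, expt, 0.1, 1.8)
        assert result.r_factor == pytest.approx(0.0, abs=1e-12)
        assert result.eta == pytest.approx(2.0)

    def test_matches_dense_grid_scan_oracle(self, theoretical, rng):
        noise = 1 + 0.05 * rng.standard_normal(len(theoretical))
        expt = ScatterCurve(q=theoretical.q, i=1.7 * theoretical.i * noise,
                            kind="experimental")
        result = sc.r_factor(theoretical, expt, 0.05, 1.9)
        _, ie, it = sc.match_q_grid(theoretical, expt, 0.05, 1.9)
        r_oracle, eta_oracle, r_coarse = grid_scan_rfactor(ie, it)
        assert result.r_factor == pytest.approx(r_oracle, abs=1e-4)
        assert result.eta == pytest.approx(eta_oracle, rel=1e-3)
        # exact minimizer never exceeds the grid-scan minimum
        assert result.r_factor <= r_oracle + 1e-12
        # convexity: the coarse scan shows a single descent-ascent pattern
        sign_changes = np.sum(np.abs(np.diff(np.sign(np.diff(r_coarse)))) > 0)
        assert sign_changes <= 2

    def test_zero_experimental_sum_rejected(self, theoretical):
        expt = ScatterCurve(q=theoretical.q, i=np.zeros(len(theoretical)),
                            kind="experimental")
        with pytest.raises(ValueError, match="zero"):
            sc.r_factor(theoretical, expt, 0.1, 1.8)
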