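import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import logit
from scipy.stats import kstest, norm

from eblrm import (
    Axis,
    FeatureSpec,
    FittedLRM,
    MMISpace,
    ProbabilityDistribution,
    UncertaintySpec,
    analytic_distribution,
    classify_modality,
    entropy,
    logit_normal_pdf,
    mean_p_vs_sigma,
    propagate_mc,
)
from eblrm.features import ConfigurationError


def uspec_for(roi, sigma_axis=None, sigma=0.0, **means):
    sigmas = {n: 0.0 for n in roi.names}
    if sigma_axis:
        sigmas[sigma_axis] = sigma
    return UncertaintySpec(dict(means), sigmas)


SET1 = dict(ca_i_ini=150, ca_sr_ini=500, g_k1_sf=0.338, k_ryr_sf=1)


def linear_1d_model():
    space = MMISpace((Axis("x", 0.0, 10.0),))
    return FittedLRM(space=space, spec=FeatureSpec.linear_only(space),
                     intercept=-1.0, weights=np.array([4.0]))


class TestPropagateMC:
    def test_no_uncertainty_degenerates_to_point_prediction(self, ref_model, roi):
        u = uspec_for(roi, **SET1)
        d = propagate_mc(ref_model, u, n_samples=1000, seed=0)
        assert d.sd == pytest.approx(0.0, abs=1e-12)
        assert d.mean == pytest.approx(0.5, abs=1e-3)
        assert entropy(d) == pytest.approx(0.0, abs=1e-12)
        assert classify_modality(d) == "unimodal"

    def test_masses_normalised_and_moments_consistent(self, ref_model, roi):
        u = uspec_for(roi, "ca_sr_ini", 30.0, **SET1)
        d = propagate_mc(ref_model, u, n_samples=50_000, seed=1)
        assert d.masses.sum() == pytest.approx(1.0, abs=1e-12)
        assert d.mean == pytest.approx(d.samples.mean())
        assert 0.0 <= d.mean <= 1.0 and d.sd <= 0.5

    def test_symmetric_anchor_keeps_mean_at_half(self, ref_model, roi):
        for sigma in (5.0, 15.0, 30.0):
            u = uspec_for(roi, "ca_sr_ini", sigma, **SET1)
            d = propagate_mc(ref_model, u, n_samples=100_000, seed=2)
            assert abs(d.mean - 0.5) < 0.02, sigma

    def test_mismatched_axes_rejected(self, ref_model):
        with pytest.raises(ConfigurationError):
            propagate_mc(ref_model, UncertaintySpec({"x": 1.0}, {"x": 0.0}))


class TestLogitNormal:
    def test_density_at_center_closed_form(self):
        # mu=0, sigma=1 at p=0.5: 4/sqrt(2 pi)
        assert logit_normal_pdf(0.5, 0.0, 1.0) == pytest.approx(
            4 / math.sqrt(2 * math.pi), abs=1e-12
        )
        assert logit_normal_pdf(0.5, 0.0, 1.0) == pytest.approx(1.5958, abs=1e-4)

    @pytest.mark.parametrize("mu, sigma", [(0.0, 1.0), (0.3, 1.2), (-2.0, 0.5)])
    def test_integrates_to_one(self, mu, sigma):
        val, err = quad(lambda p: logit_normal_pdf(p, mu, sigma),
                        1e-12, 1 - 1e-12, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1])
    def test_boundary_p_rejected(self, p):
        with pytest.raises(ValueError):
            logit_normal_pdf(p, 0.0, 1.0)

    def test_matches_mc_for_linear_model(self):
        m = linear_1d_model()
        u = UncertaintySpec({"x": 4.0}, {"x": 1.0})
        mc = propagate_mc(m, u, n_samples=100_000, seed=3)
        mu_y = m.linear_predictor(np.array([4.0]))
        sigma_y = 4.0 * 1.0 / 10.0  # |weight| * sigma / axis range
        ks = kstest(mc.samples, lambda p: norm.cdf((logit(p) - mu_y) / sigma_y))
        assert ks.statistic < 0.01


class TestAnalyticDistribution:
    def test_linear_model_matches_mc_within_mc_se(self):
        m = linear_1d_model()
        u = UncertaintySpec({"x": 4.0}, {"x": 1.0})
        ana = analytic_distribution(m, u)
        assert ana is not None and ana.analytic
        n = 200_000
        mc = propagate_mc(m, u, n_samples=n, seed=4)
        assert ana.mean == pytest.approx(mc.mean, abs=3 * 0.5 / math.sqrt(n))
        assert ana.sd == pytest.approx(mc.sd, abs=0.005)
        assert ana.masses.sum() == pytest.approx(1.0, abs=1e-12)

    def test_quadratic_involvement_is_not_applicable(self, ref_model, roi):
        # SR load enters through a square term: no closed form
        assert analytic_distribution(
            ref_model, uspec_for(roi, "ca_sr_ini", 30.0, **SET1)
        ) is None

    def test_two_uncertain_axes_not_applicable(self, ref_model, roi):
        u = UncertaintySpec(
            dict(SET1), {"ca_i_ini": 10.0, "ca_sr_ini": 10.0, "g_k1_sf": 0.0, "k_ryr_sf": 0.0}
        )
        assert analytic_distribution(ref_model, u) is None


class TestEntropyAndModality:
    def test_point_mass_has_zero_entropy(self):
        masses = np.zeros(100)
        masses[50] = 1.0
        d = ProbabilityDistribution(np.linspace(0, 1, 101), masses, 0.5, 0.0, 1)
        assert entropy(d) == 0.0
        assert classify_modality(d) == "unimodal"

    def test_uniform_masses_reach_log_bin_count(self):
        d = ProbabilityDistribution(np.linspace(0, 1, 101), np.full(100, 0.01), 0.5,
                                    math.sqrt(1 / 12), 1)
        assert entropy(d) == pytest.approx(math.log(100), abs=1e-12)
        assert classify_modality(d) == "uniform_like"

    def test_entropy_bounded_by_log_bins(self, ref_model, roi):
        u = uspec_for(roi, "ca_sr_ini", 15.0, **SET1)
        d = propagate_mc(ref_model, u, n_samples=100_000, seed=5)
        assert 0.0 <= entropy(d) <= math.log(len(d.masses))

    def test_sr_uncertainty_entropy_peaks_at_intermediate_sigma(self, ref_model, roi):
        ents = {}
        for sigma in (5.0, 15.0, 30.0):
            u = uspec_for(roi, "ca_sr_ini", sigma, **SET1)
            ents[sigma] = entropy(propagate_mc(ref_model, u, n_samples=200_000, seed=6))
        assert ents[15.0] > ents[5.0] and ents[15.0] > ents[30.0]

    @pytest.mark.parametrize(
        "sigma, expected", [(5.0, "unimodal"), (15.0, "uniform_like"), (30.0, "bimodal")]
    )
    def test_sr_uncertainty_modality_sequence(self, ref_model, roi, sigma, expected):
        u = uspec_for(roi, "ca_sr_ini", sigma, **SET1)
        d = propagate_mc(ref_model, u, n_samples=200_000, seed=7)
        assert classify_modality(d) == expected

    @pytest.mark.parametrize("g_k1", [0.638, 0.0])
    def test_off_center_sets_stay_unimodal_at_sigma30(self, ref_model, roi, g_k1):
        u = uspec_for(roi, "ca_sr_ini", 30.0, **{**SET1, "g_k1_sf": g_k1})
        d = propagate_mc(ref_model, u, n_samples=200_000, seed=8)
        assert classify_modality(d) == "unimodal"


class TestMeanVsSigma:
    def test_zero_sigma_equals_point_prediction(self, ref_model, roi):
        u = uspec_for(roi, **SET1)
        _, means = mean_p_vs_sigma(ref_model, u, "ca_sr_ini", [0.0], seed=9)
        assert means[0] == pytest.approx(0.5, abs=1e-3)

    def test_monotone_approach_toward_half(self, ref_model, roi):
        # below-center set climbs, above-center set descends (2x MC-SE slack)
        grid = np.array([0.0, 20.0, 40.0, 60.0, 80.0, 100.0])
        n = 100_000
        tol = 2 * 0.5 / math.sqrt(n)
        u2 = uspec_for(roi, **{**SET1, "g_k1_sf": 0.638})
        _, means2 = mean_p_vs_sigma(ref_model, u2, "ca_sr_ini", grid, n_samples=n, seed=10)
        assert np.all(np.diff(means2) > -tol)
        u3 = uspec_for(roi, **{**SET1, "g_k1_sf": 0.0})
        _, means3 = mean_p_vs_sigma(ref_model, u3, "ca_sr_ini", grid, n_samples=n, seed=11)
        assert np.all(np.diff(means3) < tol)

    def test_decreasing_grid_rejected(self, ref_model, roi):
        with pytest.raises(ValueError):
            mean_p_vs_sigma(ref_model, uspec_for(roi, **SET1), "ca_sr_ini", [10.0, 5.0])
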