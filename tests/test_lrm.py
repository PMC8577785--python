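import math

import numpy as np
import pytest
from scipy.special import logit

from eblrm import (
    Axis,
    BatchObservation,
    FeatureSpec,
    FitError,
    FittedLRM,
    MMISpace,
    SeparationError,
    derive_intercept_from_anchor,
    fit_lrm,
    submodel,
    validate,
)
from tests.conftest import make_observations


def space_1d(lo=0.0, hi=1.0) -> MMISpace:
    return MMISpace((Axis("x", lo, hi),))


def obs_1d(space, xs, ks, n):
    return [
        BatchObservation(point=np.array([x]), k=k, n=n) for x, k in zip(xs, ks)
    ]


class TestFit:
    def test_two_point_closed_form(self):
        # saturated 2-parameter fit: logit(0.731) ~ +1 at x=1, logit(0.269) ~ -1 at x=0
        space = space_1d()
        obs = obs_1d(space, [0.0, 1.0], [26_900, 73_100], 100_000)
        m = fit_lrm(obs, space, FeatureSpec.linear_only(space))
        assert m.intercept == pytest.approx(logit(0.269), abs=1e-6)
        assert m.weights[0] == pytest.approx(logit(0.731) - logit(0.269), abs=1e-6)
        assert m.weights[0] == pytest.approx(2.0, abs=0.01)

    def test_constant_half_counts_give_zero_weights(self, roi):
        rng = np.random.default_rng(5)
        pts = roi.lower + rng.random((30, 4)) * (roi.upper - roi.lower)
        obs = [BatchObservation(p, k=50, n=100) for p in pts]
        m = fit_lrm(obs, roi, FeatureSpec.linear_only(roi))
        assert m.intercept == pytest.approx(0.0, abs=1e-8)
        assert m.weights == pytest.approx(np.zeros(4), abs=1e-8)

    def test_matches_statsmodels_glm(self, roi, toy_config):
        # independent oracle: same counts, same design, statsmodels IRLS
        sm = pytest.importorskip("statsmodels.api")
        from eblrm import sample_roi

        pts = sample_roi(roi, 80, np.random.default_rng(21))
        obs = make_observations(toy_config, pts, 500, seed=22)
        spec = FeatureSpec.linear_only(roi)
        mine = fit_lrm(obs, roi, spec)

        from eblrm.features import expand_features, scale_mmi

        X = np.column_stack(
            [np.ones(len(obs)), expand_features(scale_mmi(pts, roi), spec, roi)]
        )
        y = np.array([[o.k, o.n - o.k] for o in obs], dtype=float)
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert mine.intercept == pytest.approx(res.params[0], rel=1e-6)
        assert mine.weights == pytest.approx(res.params[1:], rel=1e-6)
        assert mine.intercept_se == pytest.approx(res.bse[0], rel=1e-4)
        assert np.asarray(mine.se) == pytest.approx(res.bse[1:], rel=1e-4)
        assert mine.log_likelihood == pytest.approx(res.llf, rel=1e-9)

    def test_recovers_generating_weights_within_3se(self, roi, toy_config, roi_observations):
        spec = FeatureSpec.from_names(list(toy_config.true_weights))
        m = fit_lrm(roi_observations, roi, spec)
        truth = np.array(
            [toy_config.true_intercept] + list(toy_config.true_weights.values())
        )
        est = np.concatenate([[m.intercept], m.weights])
        se = np.concatenate([[m.intercept_se], m.se])
        within = np.abs(est - truth) <= 3 * se
        assert within.mean() >= 0.95

    def test_too_few_observations_is_degrees_of_freedom_error(self, roi, toy_config):
        pts = [roi.lower + 0.1 * i for i in range(5)]
        obs = make_observations(toy_config, pts, 100, seed=1)
        with pytest.raises(FitError):
            fit_lrm(obs, roi, FeatureSpec.from_names(list(toy_config.true_weights)))

    def test_complete_separation_raises(self):
        space = space_1d()
        xs = np.linspace(0, 1, 20)
        ks = [0 if x < 0.5 else 50 for x in xs]
        with pytest.raises(SeparationError):
            fit_lrm(obs_1d(space, xs, ks, 50), space, FeatureSpec.linear_only(space))

    def test_fit_invariant_under_axis_rescaling(self, roi, toy_config):
        # same data, affinely rescaled scaling bounds: identical predictions
        from eblrm import sample_roi

        pts = sample_roi(roi, 60, np.random.default_rng(31))
        obs = make_observations(toy_config, pts, 300, seed=32)
        spec = FeatureSpec.linear_only(roi)
        m1 = fit_lrm(obs, roi, spec)

        wide = MMISpace(tuple(Axis(a.name, a.lo - 50, a.hi + 50, a.units) for a in roi.axes))
        m2 = fit_lrm(obs, wide, spec)
        test_pts = sample_roi(roi, 50, np.random.default_rng(33))
        assert m1.predict_probability(test_pts) == pytest.approx(
            m2.predict_probability(test_pts), abs=1e-8
        )


class TestPrediction:
    def test_anchor_has_zero_linear_predictor(self, ref_model, set1):
        assert ref_model.linear_predictor(set1) == pytest.approx(0.0, abs=1e-12)

    def test_hf_scenario_linear_predictor(self, ref_model, roi):
        # hand-summation oracle of the 10 weighted features + intercept
        pt = roi.point(ca_i_ini=150, ca_sr_ini=550, g_k1_sf=0.51, k_ryr_sf=1)
        assert ref_model.linear_predictor(pt) == pytest.approx(2.40, abs=0.01)

    def test_zero_weight_model_predicts_intercept(self, roi):
        m = FittedLRM(space=roi, spec=FeatureSpec.linear_only(roi),
                      intercept=1.5, weights=np.zeros(4))
        assert m.linear_predictor(roi.upper) == pytest.approx(1.5)

    def test_monotone_link_and_stability(self, roi):
        m = FittedLRM(space=roi, spec=FeatureSpec.linear_only(roi),
                      intercept=-350.0, weights=np.array([700.0, 0, 0, 0]))
        lo = m.predict_probability(roi.point(ca_i_ini=100, ca_sr_ini=300, g_k1_sf=0, k_ryr_sf=0.5))
        hi = m.predict_probability(roi.point(ca_i_ini=300, ca_sr_ini=300, g_k1_sf=0, k_ryr_sf=0.5))
        assert lo < 1e-100 and hi > 1 - 1e-12 and np.isfinite([lo, hi]).all()


class TestInterceptFromAnchor:
    def test_reference_weights_anchor(self, ref_model):
        assert ref_model.intercept == pytest.approx(-44.010, abs=1e-3)

    def test_zero_weights(self, roi, set1):
        spec = FeatureSpec.linear_only(roi)
        assert derive_intercept_from_anchor(np.zeros(4), roi, spec, set1, 0.5) == 0.0
        assert derive_intercept_from_anchor(
            np.zeros(4), roi, spec, set1, 0.73
        ) == pytest.approx(logit(0.73), abs=1e-12)
        assert logit(0.73) == pytest.approx(0.9946, abs=1e-4)

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_degenerate_anchor_probability_rejected(self, roi, set1, p):
        with pytest.raises(ValueError):
            derive_intercept_from_anchor(np.zeros(4), roi, FeatureSpec.linear_only(roi), set1, p)


class TestRanking:
    def test_reference_ranking_is_identity(self, ref_model):
        from eblrm import REFERENCE_WEIGHTS

        ranked = ref_model.rank_features()
        assert [r[0] for r in ranked] == [w[0] for w in REFERENCE_WEIGHTS]

    def test_tie_broken_by_canonical_order(self, roi):
        m = FittedLRM(space=roi, spec=FeatureSpec.linear_only(roi),
                      intercept=0.0, weights=np.array([2.0, -2.0, 3.0, -1.0]))
        names = [r[0] for r in m.rank_features()]
        assert names == ["g_k1_sf", "ca_i_ini", "ca_sr_ini", "k_ryr_sf"]


class TestSubmodel:
    def test_full_top_n_reproduces_full_fit(self, roi, toy_config, roi_observations):
        spec = FeatureSpec.from_names(list(toy_config.true_weights))
        full = fit_lrm(roi_observations, roi, spec)
        again = submodel(full, roi_observations, top_n=len(spec))
        assert again.weights == pytest.approx(full.weights, abs=1e-6)

    def test_top7_contains_all_four_linear_inputs(self, roi, toy_config, roi_observations):
        spec = FeatureSpec.from_names(list(toy_config.true_weights))
        full = fit_lrm(roi_observations, roi, spec)
        sub = submodel(full, roi_observations, top_n=7)
        assert set(roi.names) <= set(sub.spec.names)

    def test_single_dominant_feature_retained(self):
        space = space_1d()
        rng = np.random.default_rng(3)
        xs = np.linspace(0, 1, 40)
        p = 1 / (1 + np.exp(-(-2 + 4 * xs)))
        obs = obs_1d(space, xs, rng.binomial(500, p), 500)
        full = fit_lrm(obs, space, FeatureSpec.from_names(["x", "x^2"]))
        sub = submodel(full, obs, top_n=1)
        assert sub.spec.names == (full.rank_features()[0][0],)

    def test_top_n_out_of_range(self, ref_model, roi_observations):
        with pytest.raises(ValueError):
            submodel(ref_model, roi_observations, top_n=11)


class TestValidation:
    def _exact_model(self):
        space = space_1d()
        # predictions 0.25, 0.5, 0.75 at x = 0, 0.5, 1
        m = FittedLRM(space=space, spec=FeatureSpec.linear_only(space),
                      intercept=-math.log(3.0), weights=np.array([2 * math.log(3.0)]))
        obs = obs_1d(space, [0.0, 0.5, 1.0], [1, 2, 3], 4)
        return m, obs

    def test_perfect_predictions(self):
        m, obs = self._exact_model()
        rep = validate(m, obs)
        assert rep.mean_abs_error == pytest.approx(0.0, abs=1e-12)
        assert rep.r2_transition == pytest.approx(1.0, abs=1e-9)
        assert rep.n_transition == 3

    def test_mean_abs_error_arithmetic(self):
        space = space_1d()
        m = FittedLRM(space=space, spec=FeatureSpec.linear_only(space),
                      intercept=float(logit(0.3)),
                      weights=np.array([float(logit(0.6) - logit(0.3))]))
        obs = obs_1d(space, [0.0, 1.0], [1, 4], 5)  # p_hat 0.2, 0.8; pred 0.3, 0.6
        rep = validate(m, obs)
        assert rep.mean_abs_error == pytest.approx(0.15, abs=1e-9)

    def test_r2_undefined_below_three_transition_sets(self):
        m, _ = self._exact_model()
        obs = obs_1d(space_1d(), [0.0, 0.5, 1.0], [0, 2, 4], 4)  # only one in (0,1)
        rep = validate(m, obs)
        assert math.isnan(rep.r2_transition)
        assert rep.n_transition == 1

    def test_empty_observations_rejected(self, ref_model):
        with pytest.raises(ValueError):
            validate(ref_model, [])


class TestBatchObservation:
    @pytest.mark.parametrize("k, n", [(-1, 10), (11, 10), (0, 0)])
    def test_invalid_counts_rejected(self, k, n):
        with pytest.raises(ValueError):
            BatchObservation(point=np.zeros(4), k=k, n=n)
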