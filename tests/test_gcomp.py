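import numpy as np
import pytest

import mixglearn as mg
from mixglearn.gcomp import (
    DEFAULT_GRID,
    ICEBundle,
    ice,
    ice_dispersion,
    joint_nace,
    nace,
    partial_dependence,
    predict_counterfactual,
)
from mixglearn.superlearner import LearnerSpec, sl_predict


class TestPredictCounterfactual:
    def test_empty_assignment_is_identity(self, glm_fit, noiseless_dataset):
        pred = predict_counterfactual(glm_fit, noiseless_dataset, {})
        assert np.allclose(pred, sl_predict(glm_fit, noiseless_dataset.design()))

    def test_unknown_exposure_rejected(self, glm_fit, noiseless_dataset):
        with pytest.raises(KeyError):
            predict_counterfactual(glm_fit, noiseless_dataset, {"bogus": 0.0})

    def test_all_exposures_at_center_rows(self, glm_fit, noiseless_dataset):
        # setting every (centered) exposure to 0 leaves only the covariate
        # part of the linear predictor; verify on 3 rows by hand arithmetic
        ds = noiseless_dataset
        assign = {e: 0.0 for e in ds.exposure_names}
        pred = predict_counterfactual(glm_fit, ds, assign)
        glm = glm_fit.models[0]
        names = glm_fit.feature_names
        for i in range(3):
            expected = glm.intercept_
            for j, name in enumerate(names):
                if name in assign:
                    continue
                expected += glm.coef_[j] * ds.W.iloc[i][name]
            assert pred[i] == pytest.approx(expected, abs=1e-10)


class TestNace:
    def test_noiseless_linear_recovery(self, glm_fit, noiseless_dataset,
                                       noiseless_cohort):
        sd_y = noiseless_cohort.truth["sd_y"]
        est = nace(glm_fit, noiseless_dataset, "hg_maternal")
        assert est.estimate * sd_y == pytest.approx(-0.15, abs=1e-6)
        est = nace(glm_fit, noiseless_dataset, "pfoa_maternal")
        assert est.estimate * sd_y == pytest.approx(-0.14, abs=1e-6)

    def test_equals_refit_glm_oracle(self, glm_fit_noisy, linear_dataset):
        # analytic oracle: beta_hat_j * (Q75_j - Q25_j) from the linear refit
        glm = glm_fit_noisy.models[0]
        names = glm_fit_noisy.feature_names
        for exposure in linear_dataset.exposure_names:
            iqr = (linear_dataset.exposure_quantile(exposure, 75)
                   - linear_dataset.exposure_quantile(exposure, 25))
            oracle = glm.coef_[names.index(exposure)] * iqr
            est = nace(glm_fit_noisy, linear_dataset, exposure)
            assert est.estimate == pytest.approx(oracle, abs=1e-8)

    def test_null_exposure_small(self, glm_fit, noiseless_dataset):
        est = nace(glm_fit, noiseless_dataset, "pcb_maternal")
        assert abs(est.estimate) < 1e-6

    def test_equals_pd_difference(self, glm_fit_noisy, linear_dataset):
        est = nace(glm_fit_noisy, linear_dataset, "hg_maternal")
        curve = partial_dependence(
            glm_fit_noisy, linear_dataset, "hg_maternal", grid=(25.0, 75.0)
        )
        assert est.estimate == pytest.approx(
            curve.values[1] - curve.values[0], abs=1e-10
        )

    def test_degenerate_iqr_returns_zero(self, noiseless_cohort):
        df = noiseless_cohort.to_frame().copy()
        df["hg_maternal"] = 2.0  # constant exposure
        ds = mg.build_analysis_dataset(df, "bnt_cued", "maternal")
        fit = mg.fit_superlearner([LearnerSpec("glm")], ds, k=5, seed=1)
        est = nace(fit, ds, "hg_maternal")
        assert est.estimate == 0.0

    def test_invalid_percentile_order(self, glm_fit, noiseless_dataset):
        with pytest.raises(ValueError):
            nace(glm_fit, noiseless_dataset, "hg_maternal", 75, 25)


class TestJointNace:
    def test_singleton_reduces_to_nace(self, glm_fit_noisy, linear_dataset):
        single = nace(glm_fit_noisy, linear_dataset, "hg_maternal")
        joint = joint_nace(glm_fit_noisy, linear_dataset, ["hg_maternal"])
        assert joint.estimate == single.estimate

    def test_additive_linear_sums(self, glm_fit_noisy, linear_dataset):
        total = sum(
            nace(glm_fit_noisy, linear_dataset, e).estimate
            for e in linear_dataset.exposure_names
        )
        joint = joint_nace(
            glm_fit_noisy, linear_dataset, linear_dataset.exposure_names
        )
        assert joint.estimate == pytest.approx(total, abs=1e-8)
        assert joint.target.startswith("joint:")

    def test_interaction_breaks_additivity_in_true_direction(self):
        _, _, dgp = mg.make_preset("interaction")
        dgp.noise_sd = 0.0
        dgp.beta_cov = {}
        cohort = mg.generate_cohort(449, seed=55, dgp=dgp)
        ds = mg.build_analysis_dataset(cohort.to_frame(), "bnt_cued", "maternal")
        lib = [LearnerSpec("poly_mars")]  # captures product terms
        fit = mg.fit_superlearner(lib, ds, k=5, seed=2)
        pair = ["hg_maternal", "pfos_maternal"]
        # a symmetric 25/75 contrast cancels the centered product term, so
        # probe additivity with an asymmetric (50, 95) contrast where the
        # Monte-Carlo truth oracle gives a clearly nonzero gap
        lo, hi = 50.0, 95.0
        sd_y = cohort.truth["sd_y"]  # undo outcome standardization
        joint = joint_nace(fit, ds, pair, lo, hi).estimate * sd_y
        total = sum(nace(fit, ds, e, lo, hi).estimate * sd_y for e in pair)
        truth_joint = mg.true_nace(dgp, cohort.exposures, pair, lo, hi)
        truth_sum = sum(
            mg.true_nace(dgp, cohort.exposures, e, lo, hi) for e in pair
        )
        assert (truth_joint - truth_sum) > 0.05
        assert np.sign(joint - total) == np.sign(truth_joint - truth_sum)
        assert (joint - total) == pytest.approx(
            truth_joint - truth_sum, abs=0.05
        )

    def test_empty_set_rejected(self, glm_fit, noiseless_dataset):
        with pytest.raises(ValueError):
            joint_nace(glm_fit, noiseless_dataset, [])


class TestPartialDependence:
    def test_linear_curve_is_affine(self, glm_fit, noiseless_dataset):
        curve = partial_dependence(glm_fit, noiseless_dataset, "hg_maternal")
        x = np.array(
            [noiseless_dataset.exposure_quantile("hg_maternal", p)
             for p in curve.grid]
        )
        resid = curve.values - np.polyval(np.polyfit(x, curve.values, 1), x)
        assert np.abs(resid).max() < 1e-6

    def test_null_exposure_flat(self, glm_fit, noiseless_dataset):
        curve = partial_dependence(glm_fit, noiseless_dataset, "pfhxs_maternal")
        assert np.ptp(curve.values) < 1e-8

    def test_quadratic_dgp_convexity(self):
        _, _, dgp = mg.make_preset("nonlinear")
        dgp.noise_sd = 0.0
        dgp.beta_cov = {}
        cohort = mg.generate_cohort(449, seed=66, dgp=dgp)
        ds = mg.build_analysis_dataset(cohort.to_frame(), "bnt_cued", "maternal")
        fit = mg.fit_superlearner([LearnerSpec("poly_mars")], ds, k=5, seed=3)
        curve = partial_dependence(fit, ds, "pcb_maternal")
        x = np.array(
            [ds.exposure_quantile("pcb_maternal", p) for p in curve.grid]
        )
        quad = np.polyfit(x, curve.values, 2)[0]
        # convexity sign matches the positive quadratic DGP coefficient,
        # checked against direct evaluation of the DGP formula
        u = (x - np.log10(cohort.exposures["pcb_maternal"]).mean()) / (
            np.quantile(np.log10(cohort.exposures["pcb_maternal"]), 0.75)
            - np.quantile(np.log10(cohort.exposures["pcb_maternal"]), 0.25)
        )
        truth_quad = np.polyfit(x, 0.1 * u**2, 2)[0]
        assert truth_quad > 0
        assert quad > 0

    def test_grid_validation(self, glm_fit, noiseless_dataset):
        with pytest.raises(ValueError):
            partial_dependence(glm_fit, noiseless_dataset, "hg_maternal",
                               grid=(50, 25))


class TestICE:
    def test_mean_curve_matches_pd(self, glm_fit_noisy, linear_dataset):
        bundle = ice(glm_fit_noisy, linear_dataset, "hg_maternal")
        curve = partial_dependence(glm_fit_noisy, linear_dataset, "hg_maternal")
        assert np.allclose(bundle.curves.mean(axis=0), curve.values, atol=1e-10)

    def test_additive_curves_parallel(self, glm_fit, noiseless_dataset):
        bundle = ice(glm_fit, noiseless_dataset, "hg_maternal")
        assert ice_dispersion(bundle) < 1e-6

    def test_interaction_raises_dispersion(self):
        base_kwargs = dict(n=449, seed=88)
        disp = {}
        for preset in ("table3_linear", "interaction"):
            _, _, dgp = mg.make_preset(preset)
            dgp.noise_sd = 0.0
            dgp.beta_cov = {}
            cohort = mg.generate_cohort(dgp=dgp, **base_kwargs)
            ds = mg.build_analysis_dataset(cohort.to_frame(), "bnt_cued",
                                           "maternal")
            fit = mg.fit_superlearner([LearnerSpec("poly_mars")], ds, k=5, seed=4)
            disp[preset] = ice_dispersion(ice(fit, ds, "hg_maternal"))
        assert disp["interaction"] > disp["table3_linear"]

    def test_shape(self, glm_fit_noisy, linear_dataset):
        bundle = ice(glm_fit_noisy, linear_dataset, "pfoa_maternal",
                     grid=(10, 50, 90))
        assert bundle.curves.shape == (linear_dataset.n, 3)


class TestIceDispersion:
    def test_parallel_bundle_zero(self):
        curves = np.tile(np.array([0.0, 1.0, 2.0]), (5, 1)) + \
            np.arange(5)[:, None]
        bundle = ICEBundle("x", (0.0, 50.0, 100.0), curves,
                           x_values=np.array([0.0, 1.0, 2.0]))
        assert ice_dispersion(bundle) == 0.0

    def test_two_slopes_population_sd(self):
        # slopes 0 and 1 -> population sd 0.5
        x = np.array([0.0, 1.0])
        curves = np.array([[1.0, 1.0], [0.0, 1.0]])
        bundle = ICEBundle("x", (0.0, 100.0), curves, x_values=x)
        assert ice_dispersion(bundle) == pytest.approx(0.5)

    def test_monotone_in_interaction_strength(self):
        # simulation ladder: stronger product term -> larger slope spread
        values = []
        for coef in (0.0, 0.1, 0.3):
            _, _, dgp = mg.make_preset("table3_linear")
            dgp.noise_sd = 0.0
            dgp.beta_cov = {}
            if coef:
                dgp.interactions = [(("hg_maternal", "pfos_maternal"), coef)]
            cohort = mg.generate_cohort(300, seed=99, dgp=dgp)
            ds = mg.build_analysis_dataset(cohort.to_frame(), "bnt_cued",
                                           "maternal")
            fit = mg.fit_superlearner([LearnerSpec("poly_mars")], ds, k=5,
                                      seed=5)
            values.append(ice_dispersion(ice(fit, ds, "hg_maternal")))
        assert values[0] < values[1] < values[2]

    def test_single_point_rejected(self):
        bundle = ICEBundle("x", (50.0,), np.zeros((3, 1)),
                           x_values=np.array([0.0]))
        with pytest.raises(ValueError):
            ice_dispersion(bundle)


class TestPermutationInvariance:
    def test_row_order_does_not_change_estimates(self, linear_table):
        rng = np.random.default_rng(0)
        shuffled = linear_table.iloc[rng.permutation(len(linear_table))]
        shuffled = shuffled.reset_index(drop=True)
        est = {}
        for name, tab in (("orig", linear_table), ("shuf", shuffled)):
            ds = mg.build_analysis_dataset(tab, "bnt_cued", "maternal")
            fit = mg.fit_superlearner([LearnerSpec("glm")], ds, k=10, seed=3)
            est[name] = nace(fit, ds, "hg_maternal").estimate
        assert est["orig"] == pytest.approx(est["shuf"], abs=1e-10)
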