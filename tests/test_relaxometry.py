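"""Linear relaxometry model: fitting, synthesis, residuals, scenario logic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

import synthmpm as sm
from synthmpm.relaxometry import (LinearRelaxometry, RelaxometryCoefficients,
                                  fit_model, plan_correction, residual_map,
                                  residual_percent, synthesize_mt,
                                  synthesize_r1)
from synthmpm.volumes import QuantitativeMap


def _maps(mt, r2s, r1=None):
    out = [QuantitativeMap(mt, kind="MTsat"), QuantitativeMap(r2s, kind="R2star")]
    if r1 is not None:
        out.insert(0, QuantitativeMap(r1, kind="R1"))
    return out


class TestFitModel:
    def test_noiseless_recovery_to_machine_precision(self, rng):
        beta = (0.30, 0.40, 0.005)
        mt = rng.uniform(0.5, 2.5, (10, 10, 10))
        r2s = rng.uniform(10, 25, (10, 10, 10))
        r1 = beta[0] + beta[1] * mt + beta[2] * r2s
        r1m, mtm, r2m = _maps(mt, r2s, r1)
        coeffs = fit_model(r1m, mtm, r2m, np.ones(mt.shape, dtype=bool))
        assert coeffs.as_array() == pytest.approx(np.array(beta), rel=1e-10)
        assert coeffs.provenance == "fitted_subject"
        assert coeffs.n_voxels == 1000

    def test_monte_carlo_coverage_three_standard_errors(self):
        # with Gaussian residuals, each beta_hat should land within 3 SE of
        # truth in >= 95% of replicates (normal theory: ~99.7%)
        import statsmodels.api as smapi
        beta = np.array([0.32, 0.22, 0.009])
        n_vox, n_rep = 10_000, 500
        rng = np.random.default_rng(7)
        hits = np.zeros(3)
        for _ in range(n_rep):
            mt = rng.uniform(0.5, 2.5, n_vox)
            r2s = rng.uniform(10.0, 25.0, n_vox)
            r1 = beta[0] + beta[1] * mt + beta[2] * r2s \
                + 0.02 * rng.standard_normal(n_vox)
            X = np.column_stack([mt, r2s])
            est = LinearRelaxometry().fit(X, r1)
            fitted = np.array([est.intercept_, *est.coef_])
            se = smapi.OLS(r1, smapi.add_constant(X)).fit().bse
            hits += np.abs(fitted - beta) <= 3 * se
        assert np.all(hits / n_rep >= 0.95)

    def test_collinear_regressors_rejected(self, rng):
        r2s = rng.uniform(10, 25, (6, 6, 6))
        mt = 0.1 * r2s  # exactly proportional
        r1 = 0.3 + 0.2 * mt
        r1m, mtm, r2m = _maps(mt, r2s, r1)
        with pytest.raises(ValueError, match="collinear"):
            fit_model(r1m, mtm, r2m, np.ones(mt.shape, dtype=bool))

    def test_small_mask_rejected(self, rng):
        mt = rng.uniform(0.5, 2.5, (3, 3, 3))
        r2s = rng.uniform(10, 25, (3, 3, 3))
        r1 = 0.3 + 0.2 * mt + 0.01 * r2s
        mask = np.zeros(mt.shape, dtype=bool)
        mask[0, 0, :2] = True
        r1m, mtm, r2m = _maps(mt, r2s, r1)
        with pytest.raises(ValueError, match="voxels"):
            fit_model(r1m, mtm, r2m, mask)

    def test_invariant_to_voxel_order_and_masked_padding(self, rng):
        beta = (0.3, 0.25, 0.008)
        mt = rng.uniform(0.5, 2.5, 500)
        r2s = rng.uniform(10, 25, 500)
        r1 = beta[0] + beta[1] * mt + beta[2] * r2s \
            + 0.02 * rng.standard_normal(500)
        X = np.column_stack([mt, r2s])
        a = LinearRelaxometry().fit(X, r1)
        perm = rng.permutation(500)
        b = LinearRelaxometry().fit(X[perm], r1[perm])
        assert a.intercept_ == pytest.approx(b.intercept_, rel=1e-9)
        np.testing.assert_allclose(a.coef_, b.coef_, rtol=1e-9)
        # masked-out voxels (garbage values) must not affect the fit
        grid = (10, 10, 10)
        mt3 = np.full(grid, 99.0)
        r2s3 = np.full(grid, 99.0)
        r13 = np.full(grid, 99.0)
        mask = np.zeros(grid, dtype=bool)
        mask.ravel()[:500] = True
        mt3.ravel()[:500] = mt
        r2s3.ravel()[:500] = r2s
        r13.ravel()[:500] = r1
        r1m, mtm, r2m = _maps(mt3, r2s3, r13)
        coeffs = fit_model(r1m, mtm, r2m, mask)
        assert coeffs.beta0 == pytest.approx(a.intercept_, rel=1e-9)

    def test_sklearn_estimator_contract(self, rng):
        est = LinearRelaxometry(min_voxels=20)
        assert est.get_params() == {"min_voxels": 20}
        cloned = clone(est)
        X = rng.uniform(0, 2, (100, 2))
        y = 0.3 + X @ np.array([0.2, 0.01])
        cloned.fit(X, y)
        np.testing.assert_allclose(cloned.predict(X), y, rtol=1e-9)


class TestSynthesis:
    def test_intercept_only(self):
        coeffs = RelaxometryCoefficients(0.8, 0.2, 0.01)
        mt = QuantitativeMap(np.zeros((3, 3, 3)), kind="MTsat")
        r2s = QuantitativeMap(np.zeros((3, 3, 3)), kind="R2star")
        out = synthesize_r1(mt, r2s, coeffs)
        np.testing.assert_array_equal(out.values, 0.8)
        assert out.provenance == "synthetic"

    def test_identity_coefficients_pass_r1_through(self, rng):
        coeffs = RelaxometryCoefficients(0.0, 1.0, 0.0)
        r1 = QuantitativeMap(rng.uniform(0.3, 1.2, (4, 4, 4)), kind="R1")
        r2s = QuantitativeMap(rng.uniform(5, 25, (4, 4, 4)), kind="R2star")
        out = synthesize_mt(r1, r2s, coeffs)
        np.testing.assert_array_equal(out.values, r1.values)

    def test_model_consistent_data_reproduced_exactly(self, rng):
        coeffs = RelaxometryCoefficients(0.32, 0.22, 0.009)
        mt = rng.uniform(0.5, 2.5, (5, 5, 5))
        r2s = rng.uniform(10, 25, (5, 5, 5))
        r1 = coeffs.beta0 + coeffs.beta1 * mt + coeffs.beta2 * r2s
        mtm, r2m = _maps(mt, r2s)
        out = synthesize_r1(mtm, r2m, coeffs)
        np.testing.assert_allclose(out.values, r1, rtol=1e-14)

    @settings(deadline=None, max_examples=50)
    @given(b0=st.floats(-1, 1), b1=st.floats(0.05, 5), b2=st.floats(-0.1, 0.1),
           sign=st.sampled_from([-1.0, 1.0]), seed=st.integers(0, 2**31 - 1))
    def test_round_trip_is_algebraic_inverse(self, b0, b1, b2, sign, seed):
        rng = np.random.default_rng(seed)
        coeffs = RelaxometryCoefficients(b0, sign * b1, b2)
        mt = QuantitativeMap(rng.uniform(0, 3, (3, 3, 3)), kind="MTsat")
        r2s = QuantitativeMap(rng.uniform(0, 30, (3, 3, 3)), kind="R2star")
        back = synthesize_mt(synthesize_r1(mt, r2s, coeffs), r2s, coeffs)
        np.testing.assert_allclose(back.values, mt.values, rtol=1e-9, atol=1e-9)

    def test_zero_beta1_rejected(self):
        with pytest.raises(ValueError, match="beta1"):
            RelaxometryCoefficients(0.3, 0.0, 0.01)

    def test_shape_mismatch_rejected(self):
        coeffs = RelaxometryCoefficients(0.3, 0.2, 0.01)
        mt = QuantitativeMap(np.zeros((3, 3, 3)), kind="MTsat")
        r2s = QuantitativeMap(np.zeros((4, 4, 4)), kind="R2star")
        with pytest.raises(ValueError, match="misaligned"):
            synthesize_r1(mt, r2s, coeffs)


class TestResiduals:
    def test_zero_for_model_consistent_data(self, rng):
        coeffs = RelaxometryCoefficients(0.32, 0.22, 0.009)
        mt = rng.uniform(0.5, 2.5, (5, 5, 5))
        r2s = rng.uniform(10, 25, (5, 5, 5))
        r1 = coeffs.beta0 + coeffs.beta1 * mt + coeffs.beta2 * r2s
        r1m, mtm, r2m = _maps(mt, r2s, r1)
        eps = residual_map(r1m, mtm, r2m, coeffs)
        np.testing.assert_allclose(eps.values, 0.0, atol=1e-12)

    def test_mean_residual_zero_over_fitted_mask(self, rng):
        mt = rng.uniform(0.5, 2.5, (8, 8, 8))
        r2s = rng.uniform(10, 25, (8, 8, 8))
        r1 = 0.3 + 0.2 * mt + 0.01 * r2s + 0.05 * rng.standard_normal(mt.shape)
        mask = rng.uniform(size=mt.shape) > 0.4
        r1m, mtm, r2m = _maps(mt, r2s, r1)
        coeffs = fit_model(r1m, mtm, r2m, mask)
        eps = residual_map(r1m, mtm, r2m, coeffs)
        assert abs(eps.values[mask].mean()) < 1e-10

    def test_residual_percent_arithmetic(self):
        measured = QuantitativeMap(np.full((2, 2, 2), 1.1), kind="MTsat")
        synthetic = QuantitativeMap(np.full((2, 2, 2), 0.9), kind="MTsat",
                                    provenance="synthetic")
        pct = residual_percent(measured, synthetic)
        np.testing.assert_allclose(pct.values, 20.0, rtol=1e-12)

    def test_residual_percent_zero_when_equal(self, rng):
        vals = rng.uniform(1, 2, (3, 3, 3))
        a = QuantitativeMap(vals, kind="MTsat")
        b = QuantitativeMap(vals.copy(), kind="MTsat", provenance="synthetic")
        np.testing.assert_array_equal(residual_percent(a, b).values, 0.0)

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_residual_percent_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = QuantitativeMap(rng.uniform(0.5, 2, (3, 3, 3)), kind="MTsat")
        b = QuantitativeMap(rng.uniform(0.5, 2, (3, 3, 3)), kind="MTsat")
        ab = residual_percent(a, b).values
        ba = residual_percent(b, a).values
        np.testing.assert_allclose(ab, -ba, rtol=1e-10)

    def test_near_zero_mean_flagged(self):
        a = QuantitativeMap(np.array([[[1.0, 1e-12]]]), kind="MTsat")
        b = QuantitativeMap(np.array([[[1.0, -1e-12]]]), kind="MTsat")
        pct = residual_percent(a, b)
        assert pct.aux["valid"][0, 0, 0]
        assert not pct.aux["valid"][0, 0, 1]


class TestScenarioLogic:
    @pytest.mark.parametrize("corrupted,action", [
        ({"MT"}, "synthesize_MT"),
        ({"T1"}, "synthesize_R1"),
        ({"PD"}, "limited_correction"),
        ({"PD", "MT"}, "limited_correction"),
        ({"PD", "T1"}, "limited_correction"),
        ({"T1", "MT"}, "limited_correction"),
        ({"PD", "T1", "MT"}, "limited_correction"),
        (set(), "none"),
    ])
    def test_decision_table(self, corrupted, action):
        decision = plan_correction(corrupted)
        assert decision.action == action
        assert decision.rationale

    def test_unknown_contrast_rejected(self):
        with pytest.raises(ValueError, match="unknown contrast"):
            plan_correction({"FLAIR"})


@pytest.fixture(scope="module")
def scenario1():
    spec = sm.PhantomSpec(noise_sigma=1.0, residual_sigma=0.01,
                          b1_field_params={"center": 1.0, "radial": 0.0},
                          seed=21)
    truth = sm.build_phantom(spec)
    session = sm.simulate_mpm_session(truth, seed=22)
    plan = sm.CorruptionPlan(target_contrast=("MT",), severity=1.0, seed=23)
    maps_clean = sm.fit_maps(session)
    maps_corr = sm.fit_maps(sm.corrupt_session(session, plan))
    coeffs = RelaxometryCoefficients(*spec.beta)
    return truth, maps_clean, maps_corr, coeffs


class TestPhantomExperiments:
    """Artefact-removal behaviour on corrupted phantom sessions (seeded)."""

    @staticmethod
    def _rmse(values, ref, mask):
        d = (values - ref)[mask]
        return float(np.sqrt(np.nanmean(d ** 2)))

    def test_synthetic_mt_beats_corrupted_measurement(self, scenario1):
        truth, _, maps_corr, coeffs = scenario1
        synth = synthesize_mt(maps_corr["r1"], maps_corr["r2star"], coeffs)
        m = truth.mask
        assert (self._rmse(synth.values, truth.mtsat, m)
                < self._rmse(maps_corr["mtsat"].values, truth.mtsat, m))

    def test_synthetic_r1_beats_corrupted_measurement_scenario2(self):
        spec = sm.PhantomSpec(noise_sigma=1.0, residual_sigma=0.01,
                              b1_field_params={"center": 1.0, "radial": 0.0},
                              seed=31)
        truth = sm.build_phantom(spec)
        session = sm.simulate_mpm_session(truth, seed=32)
        plan = sm.CorruptionPlan(target_contrast=("T1",), severity=1.0, seed=33)
        maps_corr = sm.fit_maps(sm.corrupt_session(session, plan))
        coeffs = RelaxometryCoefficients(*spec.beta)
        synth = synthesize_r1(maps_corr["mtsat"], maps_corr["r2star"], coeffs)
        m = truth.mask
        assert (self._rmse(synth.values, truth.r1, m)
                < self._rmse(maps_corr["r1"].values, truth.r1, m))

    def test_residuals_track_injected_artefact(self, scenario1):
        truth, maps_clean, maps_corr, coeffs = scenario1
        eps = residual_map(maps_corr["r1"], maps_corr["mtsat"],
                           maps_corr["r2star"], coeffs)
        art = np.abs(maps_corr["mtsat"].values - maps_clean["mtsat"].values)
        ok = truth.mask & np.isfinite(eps.values) & np.isfinite(art)
        r = np.corrcoef(np.abs(eps.values[ok]), art[ok])[0, 1]
        assert r > 0.8

    def test_fitted_beta_converges_as_residual_shrinks(self):
        errs = []
        for res_sigma in (0.05, 0.005):
            spec = sm.PhantomSpec(noise_sigma=0.0, residual_sigma=res_sigma,
                                  b1_field_params={"center": 1.0, "radial": 0.0},
                                  seed=41)
            truth = sm.build_phantom(spec)
            maps = sm.fit_maps(sm.simulate_mpm_session(truth, seed=42,
                                                       noise_sigma=0.0))
            coeffs = fit_model(maps["r1"], maps["mtsat"], maps["r2star"],
                               truth.mask)
            errs.append(np.abs(coeffs.as_array() - np.array(spec.beta)).max())
        assert errs[1] < errs[0]
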