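"""Bounded least-squares calibration: recovery, protocols, diagnostics."""

import warnings

import numpy as np
import pytest
from sklearn.base import clone

from meristree import (
    FitSpec,
    MeasurementSeries,
    StandGrowthModel,
    fit_parameters,
    generate_forcing,
    predict_stand,
    r_squared,
    refit_h2,
)
from meristree.synthetic import StandScenario, generate_stand_series, reference_parameters

YEARS = np.arange(48, 189)


@pytest.fixture(scope="module")
def forcing():
    return generate_forcing(YEARS, seed=11)


@pytest.fixture(scope="module")
def noiseless_stand(forcing):
    scenario = StandScenario(obs_noise_sd=0.0, radius_noise_sd=0.0, alpha2=0.37, seed=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return generate_stand_series(scenario, forcing)


class TestRSquared:
    def test_perfect_prediction(self):
        obs = np.array([10.0, 20.0, 30.0])
        assert r_squared(obs, obs) == 1.0

    def test_constant_mean_prediction_scores_zero(self):
        obs = np.array([10.0, 20.0, 30.0])
        assert r_squared(np.full(3, 20.0), obs) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        obs = np.array([10.0, 20.0, 30.0])
        pred = np.array([12.0, 19.0, 31.0])
        assert r_squared(pred, obs) == pytest.approx(1.0 - 6.0 / 200.0)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError):
            r_squared(np.array([1.0, 2.0]), np.array([5.0, 5.0]))

    def test_invariant_under_common_affine_rescaling(self):
        rng = np.random.default_rng(0)
        obs = rng.uniform(10, 40, 12)
        pred = obs + rng.normal(0, 1, 12)
        base = r_squared(pred, obs)
        assert r_squared(3.28 * pred + 7.0, 3.28 * obs + 7.0) == pytest.approx(base)


class TestMeasurementSeries:
    def test_decreasing_ages_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            MeasurementSeries(age=[48.0, 60.0, 55.0], height=[15.0, 18.0, 17.0])

    def test_first_record_supplies_initial(self, noiseless_stand):
        obs, truth = noiseless_stand
        r0, h0 = obs.initial
        assert r0 == pytest.approx(truth.r[0])
        assert h0 == pytest.approx(truth.h[0])


class TestFitting:
    def test_zero_free_parameters_returns_start_point(self, forcing, noiseless_stand):
        obs, _ = noiseless_stand
        ref = reference_parameters()
        res = fit_parameters(obs, forcing, FitSpec(free=()), ref, alpha2=0.37)
        assert res.params.replace(alpha2=ref.alpha2) == ref
        assert res.nfev == 1
        # the start point is the truth here, so the raw misfit is ~zero
        assert np.max(np.abs(res.residuals)) < 1e-4

    def test_noiseless_recovery_within_one_percent(self, forcing):
        free = ("Amax_over_pi", "k_lat", "h2")
        ref = reference_parameters()
        rng = np.random.default_rng(7)
        truth = ref.replace(
            Amax_over_pi=ref.Amax_over_pi * (1 + rng.uniform(-0.1, 0.1)),
            k_lat=ref.k_lat * (1 + rng.uniform(-0.3, 0.3)),
            h2=ref.h2 * (1 + rng.uniform(-0.15, 0.15)),
        )
        scenario = StandScenario(obs_noise_sd=0.0, params=truth, alpha2=0.37, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            obs, _ = generate_stand_series(scenario, forcing)
            res = fit_parameters(obs, forcing, FitSpec(free=free), ref, alpha2=0.37)
        for name in free:
            assert res.params.value_of(name) == pytest.approx(
                truth.value_of(name), rel=0.01
            )
        assert float(np.sum(res.residuals**2)) < 1e-6

    def test_noisy_fit_reaches_high_r2_within_bounds(self, forcing):
        scenario = StandScenario(obs_noise_sd=0.5, alpha2=0.37, seed=9)
        spec = FitSpec(free=("Amax_over_pi", "h2"))
        ref = reference_parameters()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            obs, _ = generate_stand_series(scenario, forcing)
            res = fit_parameters(obs, forcing, spec, ref, alpha2=0.37)
        assert res.r2 > 0.95
        for name in spec.free:
            lo = ref.value_of(name) * (1 - spec.margin(name))
            hi = ref.value_of(name) * (1 + spec.margin(name))
            assert lo <= res.params.value_of(name) <= hi

    def test_enlarging_bounds_never_increases_loss(self, forcing):
        scenario = StandScenario(obs_noise_sd=0.5, alpha2=0.37, seed=13)
        ref = reference_parameters().replace(Amax_over_pi=reference_parameters().Amax_over_pi * 0.93)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            obs, _ = generate_stand_series(scenario, forcing)
            losses = []
            for margin in (0.02, 0.10, 0.20):
                res = fit_parameters(
                    obs,
                    forcing,
                    FitSpec(free=("Amax_over_pi",), rel_bounds={"Amax_over_pi": margin}),
                    ref,
                    alpha2=0.37,
                )
                losses.append(float(np.sum(res.residuals**2)))
        assert losses[1] <= losses[0] + 1e-8
        assert losses[2] <= losses[1] + 1e-8


class TestRefitH2:
    def test_one_dimensional_recovery_of_shifted_h2(self, forcing):
        ref = reference_parameters()
        truth = ref.replace(h2=ref.h2 * 1.10)
        scenario = StandScenario(obs_noise_sd=0.0, params=truth, alpha2=0.37, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            obs, _ = generate_stand_series(scenario, forcing)
            adapted = refit_h2(obs, forcing, ref, margin=0.20, alpha2=0.37)
        assert adapted.h2 == pytest.approx(truth.h2, rel=0.02)

    def test_zero_margin_is_identity(self, forcing, noiseless_stand):
        ref = reference_parameters()
        assert refit_h2(noiseless_stand[0], forcing, ref, margin=0.0) is ref

    def test_only_h2_changes(self, forcing, noiseless_stand):
        ref = reference_parameters()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            adapted = refit_h2(noiseless_stand[0], forcing, ref, margin=0.2, alpha2=0.37)
        for name in ("g1", "C_over_pi", "C2_over_pi", "k_lat", "Amax_over_pi", "Qr", "Cr", "S1"):
            assert adapted.value_of(name) == ref.value_of(name)


class TestPrediction:
    def test_self_prediction_of_generating_stand(self, forcing, noiseless_stand):
        obs, _ = noiseless_stand
        truth_params = reference_parameters().replace(alpha2=0.37)
        pred = predict_stand(truth_params, forcing, obs.initial, obs.age)
        assert r_squared(pred["height"].to_numpy(), obs.height) > 0.99

    def test_volume_column_is_cylinder_volume(self, forcing, noiseless_stand):
        obs, _ = noiseless_stand
        truth_params = reference_parameters().replace(alpha2=0.37)
        pred = predict_stand(truth_params, forcing, obs.initial, obs.age)
        assert np.allclose(
            pred["volume"], np.pi * pred["radius"] ** 2 * pred["height"], rtol=1e-12
        )

    def test_initial_error_fans_still_bracket_truth(self, forcing, noiseless_stand):
        obs, truth = noiseless_stand
        params = reference_parameters().replace(alpha2=0.37)
        r0, h0 = obs.initial
        lo = predict_stand(params, forcing, (r0 * 0.8, h0), obs.age)
        hi = predict_stand(params, forcing, (r0 * 1.2, h0), obs.age)
        h_true = truth.height_at(obs.age)
        assert np.all(np.minimum(lo["height"], hi["height"]) <= h_true + 1e-6)
        assert np.all(np.maximum(lo["height"], hi["height"]) >= h_true - 1e-6)


class TestEstimatorAPI:
    def test_get_set_params_and_clone(self, forcing):
        model = StandGrowthModel(forcing=forcing, r0=0.075, free=("Amax_over_pi",))
        cloned = clone(model)
        assert cloned.get_params()["r0"] == 0.075
        cloned.set_params(r0=0.08)
        assert cloned.r0 == 0.08 and model.r0 == 0.075

    def test_fit_predict_score_roundtrip(self, forcing, noiseless_stand):
        obs, _ = noiseless_stand
        model = StandGrowthModel(
            params=reference_parameters(),
            forcing=forcing,
            r0=obs.initial[0],
            free=("Amax_over_pi",),
            alpha2=0.37,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model.fit(obs.age, obs.height)
            pred = model.predict(obs.age)
            score = model.score(obs.age, obs.height)
        assert pred.shape == obs.age.shape
        assert score == pytest.approx(r_squared(pred, obs.height), abs=1e-9)
        assert score > 0.999  # start point is the generating truth

    def test_unfitted_predict_rejected(self, forcing):
        from sklearn.exceptions import NotFittedError

        model = StandGrowthModel(forcing=forcing, r0=0.075)
        with pytest.raises(NotFittedError):
            model.predict(np.array([50.0, 60.0]))
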