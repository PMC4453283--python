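import numpy as np
import pytest

from agecsf import (
    CSFDataset,
    GridSpec,
    ModelComparison,
    ParameterSet,
    ViewingConditions,
    aging_predictor,
    baseline_predictor,
    compare_models,
    csf_spatial,
    grid_fit,
    rmse,
    synthesize_dataset,
)
from agecsf.optics import optical_sd, pupil_diameter

TRUTH = ParameterSet(k=3.0, u_opt=36.0, sigma0=0.50, eta=0.0330)


@pytest.fixture
def noise_free_dataset(owsley_conditions):
    return synthesize_dataset(30.0, owsley_conditions, noise_cv=0.0, seed=0, params=TRUTH)


class TestRMSE:
    def test_identical_vectors(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_single_point(self):
        assert rmse([10.0], [13.0]) == 3.0

    def test_two_points(self):
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rmse([], [])

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])


class TestGridSpec:
    def test_default_follows_protocol_ranges(self):
        g = GridSpec.default()
        assert g.eta.size == 1451 and g.eta[0] == 0.005 and g.eta[-1] == pytest.approx(0.150)
        assert g.sigma0.size == 200 and g.sigma0[0] == 0.01 and g.sigma0[-1] == pytest.approx(2.0)
        assert g.u_opt.size == 40 and g.u_opt[0] == 1.0 and g.u_opt[-1] == pytest.approx(98.5)
        assert g.k.size == 79 and g.k[0] == 0.5 and g.k[-1] == pytest.approx(20.0)
        assert np.allclose(np.diff(g.eta), 0.0001)
        assert np.allclose(np.diff(g.sigma0), 0.01)
        assert np.allclose(np.diff(g.u_opt), 2.5)
        assert np.allclose(np.diff(g.k), 0.25)

    def test_subsample(self):
        g = GridSpec.default().subsample(10)
        assert g.eta.size == 146
        assert np.allclose(np.diff(g.eta), 0.001)

    def test_invalid_axes_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(eta=np.array([]), sigma0=np.array([0.5]),
                     u_opt=np.array([30.0]), k=np.array([3.0]))
        with pytest.raises(ValueError):
            GridSpec.from_ranges(eta=(0.1, 0.05, 0.01), sigma0=(0.1, 1, 0.1),
                                 u_opt=(1, 10, 1), k=(1, 2, 1))


class TestGridFit:
    def test_noise_free_on_grid_recovery_is_exact(self, noise_free_dataset):
        result = grid_fit(noise_free_dataset, strategy="staged")
        best = result.best
        assert (best.eta, best.sigma0, best.u_opt, best.k) == (
            TRUTH.eta, TRUTH.sigma0, TRUTH.u_opt, TRUTH.k,
        )
        assert result.rmse == pytest.approx(0.0, abs=1e-9)
        assert result.best.eta in GridSpec.default().eta

    def test_reported_rmse_matches_independent_recomputation(
        self, owsley_conditions
    ):
        data = synthesize_dataset(
            30.0, owsley_conditions, noise_cv=0.05, seed=7, params=TRUTH
        )
        result = grid_fit(data, strategy="staged")
        predicted = csf_spatial(
            30.0, data.frequencies, owsley_conditions, params=result.best
        )
        assert result.rmse == pytest.approx(rmse(predicted, data.sensitivities))
        assert np.allclose(result.residuals, predicted - data.sensitivities)

    @pytest.mark.parametrize("seed", [1, 2, 3, 11])
    def test_staged_equals_exhaustive_on_reduced_grid(self, owsley_conditions, seed):
        reduced = GridSpec.default().subsample(10)
        data = synthesize_dataset(
            30.0, owsley_conditions, noise_cv=0.05, seed=seed, params=TRUTH
        )
        staged = grid_fit(data, grid=reduced, strategy="staged", coarse_factor=3)
        exhaustive = grid_fit(data, grid=reduced, strategy="exhaustive")
        assert staged.best == exhaustive.best

    def test_noisy_fit_recovers_identifiable_structure(self, owsley_conditions):
        """With 5% noise the individual optical parameters wander along the
        sigma_opt/u_opt ridge, but the identifiable quantities are stable:
        the criterion k, the optical MTF ratio sigma_opt/u_opt, and the
        overall fit quality. Bounds verified empirically over seeds and
        frozen."""
        d = pupil_diameter(30.0, 100.0, owsley_conditions.stimulus_area, 2)
        ratio_true = optical_sd(TRUTH.sigma0, d, TRUTH.cab) / TRUTH.u_opt
        data = synthesize_dataset(
            30.0, owsley_conditions, noise_cv=0.05, seed=42, params=TRUTH
        )
        best = grid_fit(data, strategy="staged").best
        assert abs(best.k - TRUTH.k) <= 0.25
        ratio_hat = optical_sd(best.sigma0, d, best.cab) / best.u_opt
        assert abs(ratio_hat - ratio_true) / ratio_true < 0.08
        fit_rmse = grid_fit(data, strategy="staged").rmse
        mean_sens = float(np.mean(data.sensitivities))
        assert fit_rmse / mean_sens < 0.12

    def test_full_exhaustive_is_gated(self, noise_free_dataset):
        with pytest.raises(ValueError, match="gated"):
            grid_fit(noise_free_dataset, strategy="exhaustive")

    def test_empty_and_mixed_age_datasets_rejected(self, owsley_conditions):
        with pytest.raises(ValueError):
            grid_fit(CSFDataset([]))
        a = synthesize_dataset(30.0, owsley_conditions, noise_cv=0.0, seed=0)
        b = synthesize_dataset(70.0, owsley_conditions, noise_cv=0.0, seed=0)
        mixed = CSFDataset(a.measurements + b.measurements)
        with pytest.raises(ValueError, match="age groups"):
            grid_fit(mixed)

    def test_unknown_strategy_rejected(self, noise_free_dataset):
        with pytest.raises(ValueError, match="strategy"):
            grid_fit(noise_free_dataset, strategy="simulated-annealing")


class TestCompareModels:
    def test_identical_models_tie(self, owsley_conditions):
        data = synthesize_dataset(30.0, owsley_conditions, noise_cv=0.05, seed=5)
        report = compare_models(data, aging_predictor(), aging_predictor(), "a", "b")
        assert report.groups[0]["winner"] == "tie"
        assert report.groups[0]["rmse_a"] == report.groups[0]["rmse_b"]

    def test_age_model_beats_baseline_on_aged_synthetic_data(self, owsley_conditions):
        data = synthesize_dataset(70.0, owsley_conditions, noise_cv=0.05, seed=3)
        report = compare_models(
            data, aging_predictor(), baseline_predictor(), "age_dependent", "baseline"
        )
        (group,) = report.groups
        assert group["winner"] == "age_dependent"
        assert group["rmse_a"] < group["rmse_b"]

    def test_json_round_trip_lossless(self, owsley_conditions):
        data = synthesize_dataset(30.0, owsley_conditions, noise_cv=0.05, seed=5)
        report = compare_models(data, aging_predictor(), baseline_predictor())
        recovered = ModelComparison.from_json(report.to_json())
        assert recovered == report
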