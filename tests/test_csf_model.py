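import math

import numpy as np
import pytest

from agecsf import (
    CSFQuery,
    TemporalFilters,
    ViewingConditions,
    barten_default_params,
    csf_barten,
    csf_spatial,
    csf_spatiotemporal,
    kstar_of_w,
    params_for_age,
)
from agecsf.optics import pupil_diameter
from agecsf.retina import inhibition_cutoff, neural_noise

from oracle import oracle_csf_barten, oracle_csf_spatial


class TestBartenBaseline:
    def test_zero_at_dc(self, keesey_conditions):
        assert csf_barten(0.0, keesey_conditions) == 0.0

    def test_matches_scalar_oracle(self, keesey_conditions):
        params = barten_default_params()
        for u in (1.0, 2.0, 4.0, 8.0, 16.0):
            assert csf_barten(u, keesey_conditions, params) == pytest.approx(
                oracle_csf_barten(u, 60.0, 7.0, 7.0, eyes=1), rel=1e-12
            )

    def test_negligible_neural_noise_closed_form(self, keesey_conditions):
        # with M_opt == 1 and Phi_neu -> 0 the curve flattens to
        # sqrt(X*Y*T / (2*Phi_opt)) / k
        params = barten_default_params().replace(sigma0=1e-12, cab=0.0, phi0=1e-30)
        from agecsf.optics import retinal_illuminance, stanley_davies_diameter
        from agecsf.retina import photon_noise

        d = stanley_davies_diameter(60.0, 49.0, 1)
        phi_opt = photon_noise(params.eta, params.p, retinal_illuminance(d, 60.0))
        expected = math.sqrt(49.0 * 0.1 / (2.0 * phi_opt)) / 3.0
        assert csf_barten(50.0, keesey_conditions, params) == pytest.approx(
            expected, rel=1e-4
        )

    def test_band_pass_peak_location(self, keesey_conditions):
        u = np.geomspace(0.1, 60.0, 300)
        s = csf_barten(u, keesey_conditions)
        peak = u[int(np.argmax(s))]
        assert 1.0 <= peak <= 8.0
        # rises before the peak, falls after
        assert s[0] < s.max() and s[-1] < s.max()

    def test_vanishes_at_high_frequency(self, keesey_conditions):
        assert csf_barten(1000.0, keesey_conditions) < 1e-6


class TestAgeDependentCSF:
    def test_equals_baseline_with_age_resolved_chain(self, owsley_conditions):
        age, u = 64.0, np.array([0.5, 2.0, 8.0, 22.0])
        params = params_for_age(age)
        d = pupil_diameter(age, 100.0, owsley_conditions.stimulus_area, 2)
        expected = csf_barten(
            u,
            owsley_conditions,
            params,
            pupil=d,
            u_inh=float(inhibition_cutoff(age, 0.0)),
            phi_neu=float(neural_noise(age, 0.0)),
        )
        assert np.array_equal(csf_spatial(age, u, owsley_conditions), expected)

    def test_matches_full_scalar_oracle(self, rng):
        for _ in range(30):
            age = rng.uniform(18.0, 90.0)
            u = rng.uniform(0.2, 40.0)
            cond = ViewingConditions(
                luminance=rng.uniform(12.5, 300.0),
                field_x=rng.uniform(2.0, 10.0),
                eyes=int(rng.integers(1, 3)),
                eccentricity=rng.uniform(0.0, 30.0),
            )
            expected = oracle_csf_spatial(
                u, age, cond.luminance, cond.field_x, cond.field_y,
                eyes=cond.eyes, eccentricity=cond.eccentricity,
            )
            assert csf_spatial(age, u, cond) == pytest.approx(expected, rel=1e-10)

    def test_vectorised_equals_scalar_loop(self, owsley_conditions):
        u = np.array([0.0, 0.5, 1.0, 4.0, 16.0, 32.0])
        vec = csf_spatial(40.0, u, owsley_conditions)
        loop = np.array([csf_spatial(40.0, f, owsley_conditions) for f in u])
        assert np.array_equal(vec, loop)

    def test_sensitivity_declines_with_age(self, owsley_conditions):
        ages = np.arange(20.0, 81.0, 10.0)
        for u in (2.0, 4.0, 8.0, 16.0):
            s = np.array([csf_spatial(a, u, owsley_conditions) for a in ages])
            assert np.all(np.diff(s) <= 0)

    def test_decline_concentrated_at_high_frequencies(self, owsley_conditions):
        ratio_high = csf_spatial(70.0, 16.0, owsley_conditions) / csf_spatial(
            30.0, 16.0, owsley_conditions
        )
        ratio_low = csf_spatial(70.0, 2.0, owsley_conditions) / csf_spatial(
            30.0, 2.0, owsley_conditions
        )
        assert ratio_high < ratio_low

    def test_nonnegative_everywhere(self, rng, owsley_conditions):
        u = rng.uniform(0.0, 60.0, 200)
        assert np.all(csf_spatial(33.0, u, owsley_conditions) >= 0)


class TestSpatiotemporal:
    def test_reduces_to_spatial_at_half_hz(self, owsley_conditions):
        u = np.array([0.5, 2.0, 8.0, 22.0])
        st = csf_spatiotemporal(30.0, u, 0.5, owsley_conditions)
        assert np.allclose(st, csf_spatial(30.0, u, owsley_conditions) / 1.0835, rtol=1e-12)

    def test_separable_criterion(self):
        from agecsf import k_of_age

        assert float(k_of_age(30.0)) * float(kstar_of_w(7.5)) == pytest.approx(
            7.553, abs=1e-3
        )

    def test_decreasing_in_temporal_frequency(self, owsley_conditions):
        w = np.array([0.5, 2.0, 7.5, 15.0, 30.0])
        s = np.array(
            [csf_spatiotemporal(30.0, 4.0, wi, owsley_conditions) for wi in w]
        )
        assert np.all(np.diff(s) < 0)

    def test_custom_filters_attenuate(self, owsley_conditions):
        filters = TemporalFilters(h1=lambda w: 0.5, h2=lambda w: 0.8)
        damped = csf_spatiotemporal(30.0, 4.0, 7.5, owsley_conditions, filters=filters)
        identity = csf_spatiotemporal(30.0, 4.0, 7.5, owsley_conditions)
        assert 0.0 < damped < identity

    def test_invalid_filter_values_rejected(self, owsley_conditions):
        filters = TemporalFilters(h1=lambda w: 1.5)
        with pytest.raises(ValueError):
            csf_spatiotemporal(30.0, 4.0, 7.5, owsley_conditions, filters=filters)


class TestCSFQuery:
    def test_evaluate_returns_tidy_table(self, owsley_conditions):
        q = CSFQuery(
            age=30.0, frequencies=[0.5, 4.0, 16.0], conditions=owsley_conditions
        )
        frame = q.evaluate()
        assert list(frame.columns) == ["frequency_cpd", "sensitivity", "log10_sensitivity"]
        assert np.allclose(
            frame["sensitivity"],
            csf_spatial(30.0, np.array([0.5, 4.0, 16.0]), owsley_conditions),
        )
        assert np.allclose(
            frame["log10_sensitivity"], np.log10(frame["sensitivity"])
        )

    def test_negative_frequency_rejected(self, owsley_conditions):
        with pytest.raises(ValueError):
            CSFQuery(age=30.0, frequencies=[-1.0], conditions=owsley_conditions)
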