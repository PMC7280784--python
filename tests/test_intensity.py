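"""Damage-site normalizations, erfc tip fitting, incorporation slopes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtrepair.intensity import (
    IntensityProfile,
    IntensityTrace,
    TipFit,
    align_profiles_at_tip,
    erfc_tip_model,
    find_saturation_time,
    fit_tip_position,
    incorporation_rate,
    normalize_minmax,
    normalize_to_postdamage,
    normalize_to_predamage,
)
from mtrepair.synthetic import generate_damage_trace, generate_tip_profiles


def step_trace(pre=200.0, post0=50.0, plateau=270.0, rate=None, t_damage=30.0,
               t_total=150.0, dt=1.0):
    """Flat pre-damage level, drop at t_damage, linear rise to plateau."""
    if rate is None:
        rate = (plateau - post0) / 45.0
    t = np.arange(0.0, t_total + dt / 2, dt)
    y = np.where(t < t_damage, pre,
                 np.minimum(post0 + rate * (t - t_damage), plateau))
    return IntensityTrace(t, y, t_damage=t_damage)


class TestTraceNormalizations:
    def test_constant_trace_all_ones(self):
        t = IntensityTrace(np.arange(20.0), np.full(20, 7.0), t_damage=10.0)
        out = normalize_to_predamage(t)
        np.testing.assert_allclose(out.intensities, 1.0)

    def test_predamage_division(self):
        tr = step_trace(pre=200.0, post0=50.0, plateau=380.0)
        out = normalize_to_predamage(tr)
        assert out.intensities[-1] == pytest.approx(380.0 / 200.0)
        pre = out.times < tr.t_damage
        assert out.intensities[pre][-5:].mean() == pytest.approx(1.0)

    def test_percent_variant(self):
        tr = step_trace()
        out = normalize_to_predamage(tr, percent=True)
        assert out.intensities[0] == pytest.approx(100.0)

    @given(c=st.floats(0.1, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_gain_invariance(self, c):
        tr = step_trace()
        scaled = IntensityTrace(tr.times, c * tr.intensities,
                                t_damage=tr.t_damage)
        a = normalize_to_predamage(tr).intensities
        b = normalize_to_predamage(scaled).intensities
        np.testing.assert_allclose(a, b, rtol=1e-10)
        a = normalize_to_postdamage(tr).intensities
        b = normalize_to_postdamage(scaled).intensities
        np.testing.assert_allclose(a, b, rtol=1e-10)

    def test_postdamage_alignment_and_unity(self):
        tr = step_trace(t_damage=30.0)
        out = normalize_to_postdamage(tr)
        i0 = np.argmin(np.abs(out.times))
        assert out.times[i0] == 0.0
        assert out.intensities[i0] == 1.0

    def test_fold_change_tubulin_alone(self):
        # recovery from 50 to plateau 270 reads out as 5.4-fold
        out = normalize_to_postdamage(step_trace(post0=50.0, plateau=270.0))
        assert out.intensities[-1] == pytest.approx(5.4)

    def test_fold_change_with_clasp(self):
        # recovery from 100 to 190 reads out as 1.9-fold
        out = normalize_to_postdamage(step_trace(post0=100.0, plateau=190.0))
        assert out.intensities[-1] == pytest.approx(1.9)

    def test_nonpositive_reference_rejected(self):
        t = np.arange(10.0)
        with pytest.raises(ValueError):
            normalize_to_predamage(
                IntensityTrace(t, np.zeros(10), t_damage=5.0)
            )


class TestMinMax:
    def test_endpoints_and_midpoint(self):
        prof = IntensityProfile(np.arange(5) * 0.1, [3.0, 5.0, 4.0, 7.0, 3.0])
        out = normalize_minmax(prof)
        assert out.intensities.min() == 0.0
        assert out.intensities.max() == 100.0
        assert out.intensities[1] == pytest.approx(50.0)

    def test_monotone_preserved(self):
        prof = IntensityProfile(np.arange(6) * 0.1,
                                [1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
        out = normalize_minmax(prof)
        assert np.all(np.diff(out.intensities) > 0)

    def test_constant_profile_rejected(self):
        prof = IntensityProfile(np.arange(5) * 0.1, np.full(5, 2.0))
        with pytest.raises(ValueError):
            normalize_minmax(prof)


class TestTipFit:
    def test_noiseless_recovery(self):
        x = np.arange(0.0, 10.0, 0.065)
        y = erfc_tip_model(x, 100.0, 10.0, 5.0, 0.3)
        fit = fit_tip_position(IntensityProfile(x, y))
        assert fit.i_mt == pytest.approx(100.0, rel=1e-3)
        assert fit.i_bg == pytest.approx(10.0, rel=1e-3)
        assert fit.x_pf == pytest.approx(5.0, rel=1e-3)
        assert fit.sigma == pytest.approx(0.3, rel=1e-3)

    def test_constant_offset_moves_background_only(self):
        x = np.arange(0.0, 10.0, 0.065)
        y = erfc_tip_model(x, 100.0, 10.0, 5.0, 0.3)
        f0 = fit_tip_position(IntensityProfile(x, y))
        f1 = fit_tip_position(IntensityProfile(x, y + 25.0))
        assert f1.i_bg == pytest.approx(f0.i_bg + 25.0, rel=1e-3)
        assert f1.i_mt == pytest.approx(f0.i_mt, rel=1e-3)
        assert f1.x_pf == pytest.approx(f0.x_pf, abs=1e-4)
        assert f1.sigma == pytest.approx(f0.sigma, rel=1e-3)

    def test_generator_truth_recovered(self):
        for prof, truth in generate_tip_profiles(5, seed=2, noise_sd=0.0):
            fit = fit_tip_position(prof)
            assert fit.x_pf == pytest.approx(truth.x_pf, abs=1e-3)
            assert fit.sigma == pytest.approx(truth.sigma, rel=1e-3)

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            fit_tip_position(IntensityProfile(np.arange(5) * 0.1,
                                              np.arange(5.0)))


class TestAlignProfiles:
    def _erfc_profile(self, x_pf, x0=0.0):
        x = np.arange(x0, x0 + 10.0, 0.065)
        return IntensityProfile(x, erfc_tip_model(x, 100.0, 10.0, x_pf, 0.3))

    def test_single_profile_tip_at_zero(self):
        prof = self._erfc_profile(4.0)
        fit = fit_tip_position(prof)
        out = align_profiles_at_tip([prof], [fit])
        mid = np.interp(0.0, out.positions, out.mean)
        assert mid == pytest.approx(60.0, rel=0.01)  # half plateau + bg

    def test_identical_profiles_different_offsets(self):
        p1, p2 = self._erfc_profile(4.0), self._erfc_profile(6.0, x0=2.0)
        fits = [fit_tip_position(p) for p in (p1, p2)]
        out = align_profiles_at_tip([p1, p2], fits)
        np.testing.assert_allclose(out.sd, 0.0, atol=1e-6)

    def test_mean_matches_template(self):
        profs = [self._erfc_profile(x) for x in (4.0, 5.0, 5.5)]
        fits = [fit_tip_position(p) for p in profs]
        out = align_profiles_at_tip(profs, fits)
        template = erfc_tip_model(out.positions, 100.0, 10.0, 0.0, 0.3)
        assert np.max(np.abs(out.mean - template)) < 0.5  # interp error

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            align_profiles_at_tip([], [])


class TestIncorporationRate:
    def test_exact_line(self):
        t = np.arange(0.0, 60.0)
        tr = IntensityTrace(t, 1.0 + 0.1 * t, t_damage=0.0)
        fit = incorporation_rate(tr, window_end=45.0)
        assert fit.slope == pytest.approx(0.1)
        assert fit.intercept == pytest.approx(1.0)

    def test_window_confined_to_rising_phase(self):
        norm = normalize_to_postdamage(step_trace(post0=50.0, plateau=270.0))
        fit = incorporation_rate(norm, window_end=40.0)
        assert fit.slope == pytest.approx((270.0 / 50.0 - 1.0) / 45.0,
                                          rel=0.01)

    def test_slope_ratio_between_conditions(self):
        # constructed traces whose true rate ratio is 1.7
        a = normalize_to_postdamage(step_trace(post0=100.0, rate=1.7,
                                               plateau=300.0))
        b = normalize_to_postdamage(step_trace(post0=100.0, rate=1.0,
                                               plateau=300.0))
        fa = incorporation_rate(a, window_end=40.0)
        fb = incorporation_rate(b, window_end=40.0)
        assert fa.slope / fb.slope == pytest.approx(1.7, rel=0.02)

    def test_linearity_in_deviation(self):
        t = np.arange(0.0, 50.0)
        base = IntensityTrace(t, 1.0 + 0.05 * t, t_damage=0.0)
        scaled = IntensityTrace(t, 1.0 + 3.0 * 0.05 * t, t_damage=0.0)
        r1 = incorporation_rate(base, 45.0).slope
        r3 = incorporation_rate(scaled, 45.0).slope
        assert r3 == pytest.approx(3.0 * r1)

    def test_too_few_samples_rejected(self):
        t = np.arange(0.0, 50.0, 10.0)
        tr = IntensityTrace(t, 1.0 + 0.1 * t, t_damage=0.0)
        with pytest.raises(ValueError):
            incorporation_rate(tr, window_end=10.0)


def test_saturation_changepoint_near_truth():
    trace, truth = generate_damage_trace(noise_sd=2.0, seed=5)
    norm = normalize_to_postdamage(trace)
    t_star = find_saturation_time(norm)
    assert t_star == pytest.approx(truth["t_saturation"] - trace.t_damage,
                                   abs=5.0)
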