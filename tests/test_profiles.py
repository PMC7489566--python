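"""Intensity-profile tracing, detrending and statistics."""

import numpy as np
import pytest

from collesmetrics.profiles import (
    ProfileTrace,
    detrend,
    measure_profiles,
    profile_statistics,
    trace_profile,
)


def _trace(intensity, offset=30.0):
    intensity = np.asarray(intensity, dtype=float)
    return ProfileTrace(
        angle_offset_deg=offset,
        positions_px=np.arange(intensity.size, dtype=float),
        intensity=intensity,
        terminated=True,
    )


class TestTraceProfile:
    def test_phantom_distance_recovered(self, flat_phantom):
        radiograph, truth = flat_phantom
        for offset in (30.0, 45.0):
            trace = trace_profile(
                radiograph.pixels,
                truth.landmarks.lunate,
                truth.landmarks.styloid,
                offset,
            )
            assert trace.terminated
            assert trace.positions_px.size == pytest.approx(
                truth.profile_distances[offset], abs=3
            )

    @pytest.mark.parametrize("offset", [30.0, 45.0])
    def test_traced_angle_matches_requested_offset(self, flat_phantom, offset):
        radiograph, truth = flat_phantom
        trace = trace_profile(
            radiograph.pixels,
            truth.landmarks.lunate,
            truth.landmarks.styloid,
            offset,
        )
        baseline = np.asarray(truth.landmarks.lunate) - np.asarray(
            truth.landmarks.styloid
        )
        baseline /= np.linalg.norm(baseline)
        cosang = float(np.clip(np.dot(baseline, trace.direction), -1, 1))
        assert np.degrees(np.arccos(cosang)) == pytest.approx(offset, abs=0.5)

    def test_styloid_on_dark_background_errors(self, flat_phantom):
        radiograph, truth = flat_phantom
        dark = (100.0, 100.0)  # background corner, far from any bone
        with pytest.raises(ValueError, match="immediately terminated"):
            trace_profile(radiograph.pixels, truth.landmarks.lunate, dark, 30.0)

    def test_invalid_offset_rejected(self, flat_phantom):
        radiograph, truth = flat_phantom
        with pytest.raises(ValueError, match="30 or 45"):
            trace_profile(
                radiograph.pixels,
                truth.landmarks.lunate,
                truth.landmarks.styloid,
                60.0,
            )

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            _trace([1.0, 2.0, 3.0])


class TestDetrend:
    def test_perfect_ramp_cancels_exactly(self):
        adjusted = detrend(_trace(2.0 * np.arange(50)))
        np.testing.assert_allclose(adjusted, 0.0, atol=1e-9)

    def test_constant_profile_cancels(self):
        np.testing.assert_allclose(detrend(_trace(np.full(30, 9.0))), 0.0, atol=1e-9)

    def test_ramp_plus_sinusoid_matches_normal_equation_oracle(self):
        # the ramp is absorbed exactly by the linear fit, so the residual is
        # the sinusoid minus its own least-squares line, computed here from
        # the closed-form normal equations
        t = np.arange(200, dtype=float)
        wave = np.sin(2 * np.pi * t / 10)
        adjusted = detrend(_trace(3.0 * t + 40.0 + wave))
        slope = np.sum((t - t.mean()) * (wave - wave.mean())) / np.sum(
            (t - t.mean()) ** 2
        )
        intercept = wave.mean() - slope * t.mean()
        np.testing.assert_allclose(adjusted, wave - (intercept + slope * t), atol=1e-6)


class TestStatistics:
    def test_analytic_line(self):
        stats = profile_statistics(_trace(3.0 * np.arange(40) + 7.0))
        assert stats.slope_full == pytest.approx(3.0)
        assert stats.slope_short == pytest.approx(3.0)
        assert stats.std_adjusted == pytest.approx(0.0, abs=1e-9)
        assert stats.distance == 40

    def test_iid_noise_keeps_raw_and_adjusted_std_close(self, rng):
        ratios = [
            profile_statistics(_trace(rng.normal(50, 5, 80))).std_adjusted
            / profile_statistics(_trace(rng.normal(50, 5, 80))).std_raw
            for _ in range(100)
        ]
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_adjusted_std_never_exceeds_raw(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 200))
            trace = _trace(rng.normal(0, rng.uniform(0.1, 20), n) + rng.uniform(-3, 3) * np.arange(n))
            stats = profile_statistics(trace)
            assert stats.std_adjusted <= stats.std_raw + 1e-12

    def test_distance_equals_sample_count(self, rng):
        trace = _trace(rng.uniform(10, 20, 37))
        assert profile_statistics(trace).distance == 37

    def test_translation_invariance_of_trace_intensities(self, rng):
        # for a fixed trace, adding a constant shifts no slope and no std
        # (the termination rule itself is contrast-relative, so translation
        # invariance is a property of the statistics, not of the tracing)
        values = rng.normal(50, 5, 80) + 0.8 * np.arange(80)
        a = profile_statistics(_trace(values))
        b = profile_statistics(_trace(values + 100.0))
        assert b.slope_full == pytest.approx(a.slope_full, abs=1e-9)
        assert b.slope_short == pytest.approx(a.slope_short, abs=1e-9)
        assert b.std_raw == pytest.approx(a.std_raw, abs=1e-9)
        assert b.std_adjusted == pytest.approx(a.std_adjusted, abs=1e-9)


class TestMeasureProfiles:
    def test_ten_named_statistics(self, flat_phantom):
        radiograph, truth = flat_phantom
        out = measure_profiles(
            radiograph.pixels, truth.landmarks.lunate, truth.landmarks.styloid
        )
        assert len(out) == 10
        for idx in (1, 2):
            assert f"Slope profile {idx} (full line)" in out
            assert out[f"Std profile {idx} adjusted"] <= out[f"Std profile {idx}"] + 1e-12
            assert out[f"Distance profile {idx}"] > 0
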