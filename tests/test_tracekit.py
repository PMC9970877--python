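"""Geometry, smoothing, derivative and imaging-correction behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from phaseflux import synthdata
from phaseflux.tracekit import (
    assemble_continuous_series,
    derivatives,
    detrend_by_lowess,
    flatfield_correct,
    lowess_smooth,
    savgol_smooth,
    spheroid_geometry,
)


class TestSpheroidGeometry:
    def test_sphere_limit_exact(self):
        v, s = spheroid_geometry(1.0, 1.0)
        assert v == pytest.approx(4 * np.pi / 3, abs=1e-12)
        assert s == pytest.approx(4 * np.pi, abs=1e-12)

    def test_prolate_volume_closed_form(self):
        v, _ = spheroid_geometry(2.0, 1.0)
        assert v == pytest.approx(8 * np.pi / 3, abs=1e-12)

    def test_prolate_surface_matches_revolution_integral(self):
        # independent oracle: surface of revolution of the ellipse
        # x = R cos(u), y = r sin(u) about the major axis
        R, r = 2.0, 1.0

        def integrand(u):
            dx = -R * np.sin(u)
            dy = r * np.cos(u)
            return 2 * np.pi * (r * np.sin(u)) * np.hypot(dx, dy)

        oracle, _ = quad(integrand, 0, np.pi / 2)
        oracle *= 2
        _, s = spheroid_geometry(R, r)
        assert s == pytest.approx(oracle, rel=1e-8)
        assert s == pytest.approx(21.4784, abs=1e-3)

    def test_swapped_radii_warn_and_fix(self):
        with pytest.warns(UserWarning):
            v, s = spheroid_geometry(1.0, 2.0)
        v2, s2 = spheroid_geometry(2.0, 1.0)
        assert v == v2 and s == s2

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            spheroid_geometry(0.0, 1.0)

    @given(
        R=st.floats(0.5, 5.0),
        r=st.floats(0.5, 5.0),
        eps=st.floats(0.01, 0.5),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_both_radii(self, R, r, eps):
        R, r = max(R, r), min(R, r)
        v0, s0 = spheroid_geometry(R, r)
        v1, s1 = spheroid_geometry(R + eps, r)
        v2, s2 = spheroid_geometry(R + eps, r + eps)
        assert v1 > v0 and v2 > v1
        assert s1 > s0 and s2 > s1


class TestSmoothers:
    def test_lowess_constant_and_line_exact(self):
        t = np.arange(40.0)
        assert np.allclose(lowess_smooth(np.full(40, 3.3), 6).values, 3.3, atol=1e-10)
        line = 0.7 * t - 2.0
        for w in (5, 9, 21):
            assert np.allclose(lowess_smooth(line, w, times=t).values, line, atol=1e-10)

    def test_lowess_denoises_sine(self):
        r = np.random.default_rng(3)
        t = np.arange(0, 300, 3.0)
        clean = np.sin(2 * np.pi * t / 100)
        noisy = clean + r.normal(0, 0.1, len(t))
        sm = lowess_smooth(noisy, 6, times=t).values
        assert np.sqrt(np.mean((sm - clean) ** 2)) < 0.1

    def test_lowess_rejects_all_missing(self):
        with pytest.raises(ValueError):
            lowess_smooth(np.full(10, np.nan), 5)

    def test_savgol_preserves_cubics(self):
        t = np.linspace(-3, 3, 41)
        y = 2 * t**3 - t**2 + 0.5 * t - 4
        for mode in ("interp", "nearest"):
            sm = savgol_smooth(y, edge_mode=mode).values
            interior = slice(3, -3) if mode == "nearest" else slice(None)
            assert np.allclose(sm[interior], y[interior], atol=1e-9)

    def test_savgol_constant_nearest_padding(self):
        assert np.allclose(savgol_smooth(np.full(20, 5.0), edge_mode="nearest").values, 5.0)

    def test_savgol_piecewise_preserves_step(self):
        y = np.concatenate([np.zeros(20), np.full(20, 10.0)])
        split = savgol_smooth(y, break_index=20).values
        blurred = savgol_smooth(y).values
        assert split[19] == pytest.approx(0.0, abs=1e-9)
        assert split[20] == pytest.approx(10.0, abs=1e-9)
        assert abs(blurred[20] - 10.0) > 0.1  # unsplit smoothing blurs the step

    def test_smoothers_are_linear_operators(self):
        r = np.random.default_rng(5)
        x, y = r.normal(size=50), r.normal(size=50)
        a, b = 1.7, -0.4
        for smooth in (
            lambda z: lowess_smooth(z, 7).values,
            lambda z: savgol_smooth(z).values,
        ):
            assert np.allclose(smooth(a * x + b * y), a * smooth(x) + b * smooth(y), atol=1e-8)


class TestDerivatives:
    def test_linear_series_both_methods(self):
        t = np.arange(0, 60, 6.0)
        y = 2.5 * t + 1.0
        assert np.allclose(derivatives(y, times=t, method="spline"), 2.5, atol=1e-9)
        mid, d = derivatives(y, times=t, method="midpoint")
        assert np.allclose(d, 2.5, atol=1e-12)
        assert np.allclose(mid, t[:-1] + 3.0)

    def test_quadratic_second_derivative_interior(self):
        t = np.arange(0, 120, 6.0)
        y = 0.3 * t**2
        d2 = derivatives(y, times=t, order=2, method="spline")
        # natural boundary conditions perturb the edges; the error decays
        # geometrically into the interior
        assert np.allclose(d2[8:-8], 0.6, atol=1e-4)

    def test_sampled_sine_derivative_tracks_cosine(self):
        t = np.arange(0, 100.1, 6.0)
        w = 2 * np.pi / 100
        d = derivatives(np.sin(w * t), times=t, method="spline")
        assert np.max(np.abs(d - w * np.cos(w * t))) < 0.02


class TestDetrend:
    def test_trend_free_oscillation_centred_on_one(self):
        t = np.arange(0, 600, 6.0)
        y = 5.0 + 0.5 * np.sin(2 * np.pi * t / 100)
        detr, _ = detrend_by_lowess(y, 40, 6, times=t)
        assert np.nanmean(detr.values) == pytest.approx(1.0, abs=0.02)

    def test_pure_exponential_trend_removed(self):
        t = np.arange(0, 600, 6.0)
        y = 3.0 * np.exp(t / 1000)
        detr, _ = detrend_by_lowess(y, 30, 6, times=t)
        assert np.allclose(detr.values, 1.0, atol=0.01)

    def test_relative_amplitude_recovered(self):
        t = np.arange(0, 900, 6.0)
        rel_amp = 0.12
        y = (1 + rel_amp * np.sin(2 * np.pi * t / 100)) * 4.0 * np.exp(t / 2000)
        # trend window much wider than the oscillation period so the slow
        # curve does not chase the oscillation
        detr, _ = detrend_by_lowess(y, 90, 6, times=t)
        v = detr.values[10:-10]
        est = np.sqrt(2) * np.std(v - np.mean(v))  # sine amplitude from its RMS
        assert est == pytest.approx(rel_amp, rel=0.10)

    def test_nonpositive_trend_rejected(self):
        y = np.linspace(1.0, -1.0, 50)
        with pytest.raises(ValueError):
            detrend_by_lowess(y, 30, 5)


class TestFlatfield:
    def test_uniform_illumination_is_baseline_subtraction(self):
        stack = synthdata.simulate_flatfield_frames({"amp": 800, "sigma": None}, 4, seed=0)
        corr = flatfield_correct(stack, stack[0])
        assert np.allclose(corr, 800.0, atol=1e-6)

    def test_gaussian_field_roundtrip_flat(self):
        stack = synthdata.simulate_flatfield_frames(
            {"amp": 1000, "center": (32, 32), "sigma": 40}, 5, seed=1, noise_sd=0.0
        )
        corr = flatfield_correct(stack, stack[0])
        assert (corr.max() - corr.min()) / corr.max() < 1e-6

    def test_blank_frame_corrects_to_zero(self):
        stack = synthdata.simulate_flatfield_frames(
            {"amp": 1000, "center": (32, 32), "sigma": 40}, 5, seed=1, noise_sd=0.0
        )
        blank = np.full((64, 64), 500.0)  # camera baseline only
        corr = flatfield_correct(stack, blank)
        assert np.allclose(corr, 0.0, atol=1e-9)

    def test_noisy_field_corner_to_centre_within_two_percent(self):
        stack = synthdata.simulate_flatfield_frames(
            {"amp": 1000, "center": (32, 32), "sigma": 40}, 15, seed=2, noise_sd=10.0
        )
        corr = flatfield_correct(stack, stack[0])
        ratio = corr[2, 2] / corr[32, 32]
        assert ratio == pytest.approx(1.0, abs=0.02)


class TestAssembleContinuous:
    def test_translation_identity_and_shift(self, clean_population):
        truth, sim = clean_population
        tr, ann = sim.traces[0], sim.annotations[0]
        cycles = assemble_continuous_series(tr, ann.events, "volume")
        for cyc in cycles[1:-1]:
            vals, t = cyc["values"], cyc["time"]
            # continuity at the cycle boundaries: no jump above the smooth
            # growth increment scale
            steps = np.abs(np.diff(vals))
            assert steps.max() < 5.0

    def test_missing_bud_frames_interpolated_linearly(self, clean_population):
        truth, sim = clean_population
        tr, ann = sim.traces[0], sim.annotations[0]
        cycles = assemble_continuous_series(tr, ann.events, "volume")
        cyc = cycles[1]
        # total volume stays continuous through the unmeasurable bud frames
        core = cyc["values"][cyc["in_cycle"]]
        assert np.all(np.isfinite(core))
        assert np.all(np.diff(core) > -1.0)

    def test_rejects_without_two_mes(self, clean_population):
        truth, sim = clean_population
        tr = sim.traces[0]
        with pytest.raises(ValueError):
            assemble_continuous_series(tr, {"ME": [50.0], "BUD": []}, "volume")
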