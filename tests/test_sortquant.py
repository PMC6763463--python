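"""Sorting/recycling quantification: masks, traces and kinetic summaries."""

import numpy as np
import pytest

from endorecycle.core import AnalysisConfig, IntensityTrace
from endorecycle.simulate import RecyclingSimParams, simulate_recycling_assay
from endorecycle.sortquant import (
    endosomal_incorporation_trace,
    exit_slope,
    format_minutes_seconds,
    half_maximal_time,
    plasma_membrane_recycling_trace,
    segment_endosomes,
    total_recycling_halftime,
    window_mean,
)

from conftest import make_movie


class TestSegmentEndosomes:
    def test_bimodal_image_recovers_bright_mode(self):
        rng = np.random.default_rng(0)
        truth = np.zeros((64, 64), bool)
        truth[10:30, 10:30] = True
        img = np.where(truth, 200.0, 20.0) + rng.normal(0, 3, (64, 64))
        mask = segment_endosomes(np.clip(img, 0, None))
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou >= 0.8

    def test_constant_image_otsu_errors(self):
        with pytest.raises(ValueError, match="Otsu"):
            segment_endosomes(np.full((10, 10), 5.0))

    def test_fixed_threshold_limits(self):
        cfg = AnalysisConfig(threshold_method="fixed", fixed_threshold=1.0, min_object_px=1)
        assert segment_endosomes(np.full((8, 8), 5.0), cfg).all()
        assert not segment_endosomes(np.zeros((8, 8)), cfg).any()


class TestIncorporationTrace:
    def _movie(self, marker_img, pa_img, n_frames=4):
        data = np.zeros((n_frames, 2, *pa_img.shape))
        data[:, 0] = pa_img
        data[:, 1] = marker_img
        return make_movie(data, names=["pa", "mk"])

    def test_full_overlap_gives_100(self, fixed_cfg):
        pa = np.zeros((32, 32))
        pa[10:13, 10:13] = 50.0
        m = self._movie(np.full((32, 32), 10.0), pa)
        tr = endosomal_incorporation_trace(m, "pa", "mk", fixed_cfg)
        assert np.allclose(tr.values, 100.0)

    def test_disjoint_marker_gives_0(self, fixed_cfg):
        pa = np.zeros((32, 32))
        pa[10:13, 10:13] = 50.0
        mk = np.zeros((32, 32))
        mk[25:30, 25:30] = 50.0
        tr = endosomal_incorporation_trace(self._movie(mk, pa), "pa", "mk", fixed_cfg)
        assert np.allclose(tr.values, 0.0)

    def test_invariant_under_cargo_rescaling(self, sorting_movie):
        _, movie, _ = sorting_movie
        tr1 = endosomal_incorporation_trace(movie, "pa_cargo", "marker")
        scaled = movie.data.copy()
        scaled[:, 0] *= 3.0
        m2 = make_movie(scaled, names=movie.channel_names,
                        pixel_size_nm=movie.pixel_size_nm, frame_interval_s=2.5)
        tr2 = endosomal_incorporation_trace(m2, "pa_cargo", "marker")
        assert np.nanmax(np.abs(tr1.values - tr2.values)) < 1e-6

    def test_tracks_simulated_occupancy(self, sorting_movie):
        _, movie, truth = sorting_movie
        tr = endosomal_incorporation_trace(movie, "pa_cargo", "marker")
        err = np.abs(tr.values - 100.0 * truth.occupancy_fraction)
        assert np.nanmax(err) <= 10.0

    def test_monotone_in_marker_mask(self, fixed_cfg):
        # a strictly larger marker mask can only raise the percentage
        rng = np.random.default_rng(1)
        pa = rng.uniform(0, 100, (32, 32))
        small = np.zeros((32, 32))
        small[8:16, 8:16] = 50.0
        big = small.copy()
        big[8:24, 8:24] = 50.0
        v_small = endosomal_incorporation_trace(self._movie(small, pa), "pa", "mk", fixed_cfg).values
        v_big = endosomal_incorporation_trace(self._movie(big, pa), "pa", "mk", fixed_cfg).values
        assert np.all(v_big >= v_small - 1e-12)

    def test_missing_channel_errors(self, sorting_movie):
        _, movie, _ = sorting_movie
        with pytest.raises(KeyError):
            endosomal_incorporation_trace(movie, "nope", "marker")


class TestExitSlope:
    def test_exact_line(self):
        t = np.arange(50.0, 151.0, 2.5)
        tr = IntensityTrace(t, 80.0 - 0.2 * t)
        fit = exit_slope(tr)
        assert fit.slope == pytest.approx(-0.2, abs=1e-12)
        assert fit.intercept == pytest.approx(80.0, abs=1e-9)
        assert fit.slope_se == 0.0

    def test_constant_trace_zero_slope(self):
        tr = IntensityTrace(np.arange(40.0, 120.0, 5.0), np.full(16, 42.0))
        assert exit_slope(tr).slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        t = np.arange(50.0, 150.0, 2.5)
        y = 60 - 0.15 * t + rng.normal(0, 2, t.shape)
        fit = exit_slope(IntensityTrace(t, y))
        # independent closed form: slope = cov(t,y)/var(t)
        slope = ((t - t.mean()) * (y - y.mean())).sum() / ((t - t.mean()) ** 2).sum()
        intercept = y.mean() - slope * t.mean()
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    def test_window_respects_regression_start(self):
        t = np.arange(0.0, 150.0, 2.5)
        y = np.where(t < 50, 100.0, 100.0 - 0.3 * (t - 50))
        fit = exit_slope(IntensityTrace(t, y))
        assert fit.window[0] == 50.0
        assert fit.slope == pytest.approx(-0.3, abs=1e-12)

    def test_too_few_points_errors(self):
        tr = IntensityTrace([0.0, 55.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            exit_slope(tr)


class TestHalfMaximalTime:
    def test_linear_ramp(self):
        t = np.arange(0.0, 101.0, 1.0)
        y = np.minimum(t, 100.0)
        y[-3:] = 100.0
        assert half_maximal_time(IntensityTrace(t, y)) == pytest.approx(50.0)

    def test_step_interpolates(self):
        tr = IntensityTrace([5.0, 7.5, 10.0, 12.5, 15.0, 17.5], [0, 0, 0, 100, 100, 100])
        assert half_maximal_time(tr) == pytest.approx(11.25)

    def test_exponential_rise_oracle(self):
        k = 0.01
        t = np.arange(0.0, 800.0, 2.5)
        tr = IntensityTrace(t, 100 * (1 - np.exp(-k * t)))
        # plateau is the late-trace mean, slightly below the asymptote
        plateau = tr.values[-3:].mean()
        expected = -np.log(1 - plateau / 200.0) / k
        assert half_maximal_time(tr) == pytest.approx(expected, abs=2.5)
        assert abs(half_maximal_time(tr) - np.log(2) / k) <= 2.5

    def test_never_reached_reports_nan(self):
        # plateau -100, half -50: the trace never rises to half the plateau
        tr = IntensityTrace(np.arange(5.0), [-200.0, -150.0, -100.0, -100.0, -100.0])
        assert np.isnan(half_maximal_time(tr))


class TestTotalHalftime:
    def test_worked_example(self):
        total = total_recycling_halftime(186.6, 375.0)
        assert total == pytest.approx(561.6)
        assert format_minutes_seconds(total) == "9 min 21.6 s"

    def test_trivial_sums(self):
        assert total_recycling_halftime(0, 0) == 0
        assert total_recycling_halftime(60, 60) == 120
        assert format_minutes_seconds(120.0) == "2 min 0 s"

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            total_recycling_halftime(-1, 10)


class TestWindowMean:
    def test_constant_and_pair(self):
        tr = IntensityTrace(np.arange(10.0), np.full(10, 42.0))
        assert window_mean(tr, 0, 9) == 42.0
        tr2 = IntensityTrace([900.0, 1000.0, 1300.0], [10.0, 20.0, 99.0])
        assert window_mean(tr2, 900, 1200) == 15.0

    def test_agrees_with_direct_sum(self):
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(0, 100, 40))
        t += np.arange(40) * 1e-6
        v = rng.normal(size=40)
        tr = IntensityTrace(t, v)
        sel = (t >= 20) & (t <= 80)
        assert window_mean(tr, 20, 80) == pytest.approx(v[sel].mean(), rel=1e-12)

    def test_empty_window_errors(self):
        tr = IntensityTrace([0.0, 1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            window_mean(tr, 5.0, 6.0)


@pytest.fixture(scope="module")
def pm_setup():
    params = RecyclingSimParams()
    movie, truth = simulate_recycling_assay(params, 3)
    band = truth.extras["pm_band"]
    h, w = movie.shape
    yy, xx = np.mgrid[0:h, 0:w]
    rr = np.sqrt((xx - w / 2) ** 2 + (yy - h / 2) ** 2)
    pm = (rr >= band["inner_px"]) & (rr <= band["outer_px"])
    return params, movie, truth, pm


class TestPlasmaMembraneRecycling:
    def test_baseline_frames_are_zero_by_construction(self, pm_setup):
        params, movie, truth, pm = pm_setup
        tr = plasma_membrane_recycling_trace(movie, "pa_cargo", pm_band=pm)
        base = tr.values[: params.n_baseline_frames]
        assert abs(np.nanmean(base)) < 5.0  # noise floor, centred on 0

    def test_tracks_truth_delivery(self, pm_setup):
        params, movie, truth, pm = pm_setup
        tr = plasma_membrane_recycling_trace(movie, "pa_cargo", pm_band=pm)
        expected = 100.0 * truth.pm_delivered_fraction / params.pm_baseline_fraction
        err = np.abs(tr.values - expected)
        assert np.nanmax(err) < 15.0

    def test_zero_recycling_flat(self):
        params = RecyclingSimParams(recycled_fraction=0.0, n_frames=20)
        movie, truth = simulate_recycling_assay(params, 2)
        h, w = movie.shape
        yy, xx = np.mgrid[0:h, 0:w]
        rr = np.sqrt((xx - w / 2) ** 2 + (yy - h / 2) ** 2)
        pm = (rr >= params.pm_band_inner_px) & (rr <= params.pm_band_outer_px)
        tr = plasma_membrane_recycling_trace(movie, "pa_cargo", pm_band=pm)
        assert abs(np.nanmean(tr.values)) < 5.0

    def test_noise_free_conservation(self):
        params = RecyclingSimParams(noise=False, background=0.0, recycled_fraction=0.5,
                                    delivery_rate_per_s=0.05, n_frames=30)
        movie, truth = simulate_recycling_assay(params, 1)
        h, w = movie.shape
        yy, xx = np.mgrid[0:h, 0:w]
        rr = np.sqrt((xx - w / 2) ** 2 + (yy - h / 2) ** 2)
        pm = (rr >= params.pm_band_inner_px) & (rr <= params.pm_band_outer_px)
        tr = plasma_membrane_recycling_trace(movie, "pa_cargo", pm_band=pm)
        expected_final = 100.0 * 0.5 / params.pm_baseline_fraction
        assert tr.values[-1] == pytest.approx(expected_final, rel=1e-6)

    def test_requires_baseline_frames(self, pm_setup):
        params, movie, truth, pm = pm_setup
        m2 = make_movie(movie.data, names=movie.channel_names,
                        pixel_size_nm=movie.pixel_size_nm, frame_interval_s=30.0,
                        pa_frames=[0])
        with pytest.raises(ValueError, match="baseline"):
            plasma_membrane_recycling_trace(m2, "pa_cargo", pm_band=pm)
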