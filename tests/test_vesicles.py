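"""Spot detection, exclusion, tracking and nearest-neighbour fractions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endorecycle.core import AnalysisConfig, RegionOfInterest
from endorecycle.simulate import render_spots, apply_camera_noise
from endorecycle.vesicles import (
    VesicleDetection,
    detect_vesicles,
    exclude_region,
    nn_fraction,
    randomized_nn_fraction,
    track_vesicles,
    vesicle_count_trace,
)

from conftest import make_movie


def _spot_field(points, shape=(128, 128), snr=5.0, bg=10.0, rn=2.0, sigma=1.5, seed=0):
    amp = snr * np.sqrt(bg + rn**2)
    img = np.full(shape, float(bg))
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts):
        render_spots(shape, pts[:, 0], pts[:, 1], amp, sigma, out=img)
    return apply_camera_noise(img, np.random.default_rng(seed), rn, poisson=True)


def _dets(points):
    return [VesicleDetection(0, float(x), float(y), 1.0, 1.0, 1.0) for x, y in points]


class TestDetect:
    def test_blank_image_empty(self):
        img = apply_camera_noise(np.full((64, 64), 10.0), np.random.default_rng(0), 2.0, True)
        assert detect_vesicles(img) == []

    def test_single_spot_subpixel(self):
        img = _spot_field([(32.0, 48.0)], shape=(96, 96), snr=10, seed=1)
        dets = detect_vesicles(img)
        assert len(dets) == 1
        assert abs(dets[0].x - 32.0) <= 0.5 and abs(dets[0].y - 48.0) <= 0.5

    def test_field_recall_precision(self):
        rng = np.random.default_rng(2)
        g = np.linspace(14, 186, 8)
        pts = np.array([(x, y) for y in g for x in g])[:50] + rng.uniform(-2, 2, (50, 2))
        img = _spot_field(pts, shape=(200, 200), snr=5, seed=2)
        dets = detect_vesicles(img)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(np.array([[v.x, v.y] for v in dets])).query(pts)
        recall = (d <= 2).mean()
        d2, _ = cKDTree(pts).query(np.array([[v.x, v.y] for v in dets]))
        precision = (d2 <= 2).mean()
        assert recall >= 0.9 and precision >= 0.9

    def test_sorted_by_peak(self):
        img = np.full((64, 64), 1.0)
        render_spots((64, 64), [16, 48], [16, 48], [50.0, 200.0], 1.5, out=img)
        dets = detect_vesicles(img)
        peaks = [d.peak_intensity for d in dets]
        assert peaks == sorted(peaks, reverse=True)


class TestExclude:
    def test_full_and_empty_masks(self):
        dets = _dets([(5, 5), (20, 20)])
        assert exclude_region(dets, np.ones((32, 32), bool)) == []
        assert exclude_region(dets, np.zeros((32, 32), bool)) == dets

    def test_boundary_pixel_belongs_to_mask(self):
        mask = np.zeros((32, 32), bool)
        mask[10, 10] = True
        dets = _dets([(10.0, 10.0)])
        assert exclude_region(dets, mask) == []

    def test_circle_roi_exclusion(self):
        roi = RegionOfInterest(shape="circle", cx=16, cy=16, r=5, role="exclusion")
        dets = _dets([(16, 16), (30, 30), (16, 21)])  # (16,21) on boundary
        kept = exclude_region(dets, roi)
        assert [(d.x, d.y) for d in kept] == [(30, 30)]


class TestTracking:
    def test_stationary_spot_single_track(self):
        frames = [[VesicleDetection(t, 10.0, 10.0, 1, 1, 1)] for t in range(20)]
        tracks = track_vesicles(frames)
        assert len(tracks) == 1 and len(tracks[0]) == 20

    def test_distant_spots_never_merge(self):
        frames = [
            [VesicleDetection(t, 5.0, 5.0, 1, 1, 1), VesicleDetection(t, 50.0, 50.0, 1, 1, 1)]
            for t in range(10)
        ]
        tracks = track_vesicles(frames)
        assert len(tracks) == 2
        for tr in tracks:
            xs = {d.x for d in tr.detections}
            assert len(xs) == 1  # never jumped between the two spots

    @pytest.mark.parametrize("method", ["greedy", "hungarian"])
    def test_brownian_purity(self, method):
        rng = np.random.default_rng(4)
        p0 = np.array([(x, y) for x in np.linspace(15, 105, 4) for y in np.linspace(15, 105, 4)])
        truth_frames = []
        pos = p0.copy()
        for t in range(15):
            pos = pos + rng.normal(0, 0.4, pos.shape)  # step << 30 px spacing
            truth_frames.append(pos.copy())
        frames = [
            [VesicleDetection(t, x, y, 1, 1, 1) for x, y in truth_frames[t]] for t in range(15)
        ]
        tracks = track_vesicles(frames, method=method)
        assert len(tracks) == 16
        # purity: every track follows one truth identity
        pure = 0
        for tr in tracks:
            ids = set()
            for d in tr.detections:
                ids.add(int(np.argmin(np.hypot(truth_frames[d.frame][:, 0] - d.x,
                                               truth_frames[d.frame][:, 1] - d.y))))
            pure += len(ids) == 1
        assert pure / len(tracks) >= 0.95

    def test_gap_closing(self):
        frames = [[VesicleDetection(t, 10.0, 10.0, 1, 1, 1)] for t in (0, 1, 3, 4)]
        tracks = track_vesicles(frames)
        assert len(tracks) == 1 and len(tracks[0]) == 4


class TestNNFraction:
    CFG = AnalysisConfig()

    def test_identical_coordinates_100(self):
        pts = np.random.default_rng(0).uniform(0, 50, (20, 2))
        assert nn_fraction(_dets(pts), _dets(pts), self.CFG, pixel_size_nm=100) == 100.0

    def test_all_far_0(self):
        a = _dets([(0, 0)])
        b = _dets([(100, 100)])
        assert nn_fraction(a, b, self.CFG, pixel_size_nm=100) == 0.0

    def test_tie_at_threshold_counts_within(self):
        a = _dets([(0.0, 0.0)])
        b = _dets([(3.2, 0.0)])  # exactly 320 nm at 100 nm/px
        assert nn_fraction(a, b, self.CFG, pixel_size_nm=100) == 100.0

    def test_empty_a_undefined(self):
        assert np.isnan(nn_fraction([], _dets([(1, 1)]), self.CFG, pixel_size_nm=100))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = _dets(rng.uniform(0, 100, (30, 2)))
        b = _dets(rng.uniform(0, 100, (30, 2)))
        fast = nn_fraction(a, b, self.CFG, pixel_size_nm=100)
        brute = 100.0 * sum(
            min(np.hypot(da.x - db.x, da.y - db.y) * 100 for db in b) <= 320 for da in a
        ) / len(a)
        assert fast == brute

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        a = _dets(rng.uniform(0, 60, (40, 2)))
        b = _dets(rng.uniform(0, 60, (40, 2)))
        vals = [
            nn_fraction(a, b, AnalysisConfig(nn_threshold_nm=thr), pixel_size_nm=100)
            for thr in (100, 320, 600, 1200)
        ]
        assert vals == sorted(vals)

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        pa = rng.uniform(10, 50, (25, 2))
        pb = rng.uniform(10, 50, (25, 2))
        v1 = nn_fraction(_dets(pa), _dets(pb), self.CFG, pixel_size_nm=100)
        v2 = nn_fraction(_dets(pa + 7.3), _dets(pb + 7.3), self.CFG, pixel_size_nm=100)
        assert v1 == pytest.approx(v2, abs=1e-9)


class TestRandomizedNN:
    CFG = AnalysisConfig()

    def test_empty_b_zero(self):
        mask = np.ones((64, 64), bool)
        a = _dets([(10, 10), (20, 20)])
        assert randomized_nn_fraction(a, mask, [], self.CFG, pixel_size_nm=100, seed=1) == 0.0

    def test_saturated_b_100(self):
        mask = np.ones((32, 32), bool)
        ys, xs = np.mgrid[0:32:2, 0:32:2]
        b = _dets(np.column_stack([xs.ravel(), ys.ravel()]))  # 2 px grid << 3.2 px radius
        a = _dets([(5, 5), (10, 10)])
        assert randomized_nn_fraction(a, mask, b, self.CFG, pixel_size_nm=100, seed=2) == 100.0

    def test_spatial_poisson_oracle(self):
        rng = np.random.default_rng(9)
        side = 300
        n_b = 200
        mask = np.ones((side, side), bool)
        b = _dets(rng.uniform(0, side, (n_b, 2)))
        a = _dets(rng.uniform(50, 250, (80, 2)))
        est = randomized_nn_fraction(a, mask, b, self.CFG, pixel_size_nm=100,
                                     n_iter=100, seed=3)
        rho = n_b / (side * side * 100 * 100)  # per nm^2
        pred = 100 * (1 - np.exp(-rho * np.pi * 320**2))
        # binomial SE of the mean over n_iter draws of 80 repositions
        se = 100 * np.sqrt(pred / 100 * (1 - pred / 100) / (80 * 100))
        assert abs(est - pred) <= max(3 * se, 1.0)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(11)
        mask = np.ones((100, 100), bool)
        a = _dets(rng.uniform(0, 100, (20, 2)))
        b = _dets(rng.uniform(0, 100, (20, 2)))
        v1 = randomized_nn_fraction(a, mask, b, self.CFG, pixel_size_nm=100, seed=5)
        v2 = randomized_nn_fraction(a, mask, b, self.CFG, pixel_size_nm=100, seed=5)
        assert v1 == v2


class TestCountTrace:
    def test_blank_movie_zero(self):
        rng = np.random.default_rng(0)
        data = rng.poisson(10.0, size=(5, 1, 64, 64)).astype(float)[:, :]
        m = make_movie(data)
        tr = vesicle_count_trace(m, 0)
        assert np.all(tr.values == 0)

    def test_constant_spot_count_with_exclusion(self):
        rng = np.random.default_rng(1)
        pts = np.array([(x, y) for x in np.linspace(12, 116, 4) for y in np.linspace(12, 116, 3)])
        frames = np.stack(
            [_spot_field(pts, shape=(128, 128), snr=10, seed=s)[None] for s in range(6)]
        )
        m = make_movie(frames)
        tr = vesicle_count_trace(m, 0)
        assert np.all(np.abs(tr.values - 12) <= 1)
        full = RegionOfInterest(shape="circle", cx=64, cy=64, r=200, role="exclusion")
        assert np.all(vesicle_count_trace(m, 0, exclusion=full).values == 0)
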