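"""Segmentation primitives against independent oracles, plus the track loop."""

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.filters import threshold_otsu as skimage_otsu

from omegaquant import ringtrack as rt
from omegaquant import synthmovie as sm

from conftest import fixed_phase_config


# ---------------------------------------------------------------------------
# ROI extraction
# ---------------------------------------------------------------------------

class TestExtractRoi:
    def test_interior_seed_full_window(self):
        frame = np.arange(512 * 512, dtype=float).reshape(512, 512)
        window, (oy, ox) = rt.extract_roi(frame, (256, 256), 50)
        assert window.shape == (50, 50)
        assert (oy, ox) == (231, 231)
        np.testing.assert_array_equal(window,
                                      frame[231:281, 231:281])

    def test_edge_seed_clipped_window(self):
        """Seed 10 px from the left edge: width 10 + 25 = 35 px."""
        frame = np.zeros((512, 512))
        window, (oy, ox) = rt.extract_roi(frame, (256, 10), 50)
        assert window.shape == (50, 35)
        assert (oy, ox) == (231, 0)

    def test_degenerate_single_pixel_roi(self):
        frame = np.arange(25, dtype=float).reshape(5, 5)
        window, off = rt.extract_roi(frame, (2, 3), 1)
        assert window.shape == (1, 1)
        assert window[0, 0] == frame[2, 3]
        assert off == (2, 3)

    def test_seed_outside_image_raises(self):
        with pytest.raises(ValueError, match="outside"):
            rt.extract_roi(np.zeros((64, 64)), (70, 10), 50)


# ---------------------------------------------------------------------------
# Otsu
# ---------------------------------------------------------------------------

def otsu_exhaustive(window):
    """Independent oracle: exhaustive maximization of between-class
    variance over all 256-bin splits, in exact rational arithmetic."""
    w = np.asarray(window, float).ravel()
    lo, hi = w.min(), w.max()
    if lo == hi:
        return float(lo)
    counts, edges = np.histogram(w, bins=256, range=(lo, hi))
    total = int(counts.sum())
    best_sb, best_edge = Fraction(-1), None
    for k in range(255):
        n0 = int(counts[:k + 1].sum())
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            continue
        m0 = Fraction(int((counts[:k + 1] * np.arange(k + 1)).sum()), n0)
        m1 = Fraction(int((counts[k + 1:]
                           * np.arange(k + 1, 256)).sum()), n1)
        sb = Fraction(n0 * n1, total * total) * (m0 - m1) ** 2
        if sb > best_sb:
            best_sb, best_edge = sb, edges[k + 1]
    return float(best_edge)


class TestOtsu:
    def test_matches_exhaustive_oracle_on_random_windows(self):
        rng = np.random.default_rng(0)
        for i in range(100):
            kind = i % 3
            if kind == 0:
                w = rng.normal(100, 10, (16, 16))
            elif kind == 1:
                w = rng.poisson(50, (16, 16)).astype(float)
            else:
                w = rng.uniform(0, 255, (16, 16))
            assert rt.otsu_threshold(w) == otsu_exhaustive(w)

    def test_agrees_with_skimage_within_one_bin(self):
        """skimage returns the bin center where we return the edge; the two
        must sit within one bin width of each other."""
        rng = np.random.default_rng(1)
        for _ in range(25):
            w = rng.normal(100, 30, (32, 32))
            bin_width = np.ptp(w) / 256
            assert abs(rt.otsu_threshold(w)
                       - skimage_otsu(w, nbins=256)) <= bin_width

    def test_two_valued_window_separates_exactly(self):
        w = np.array([[10.0] * 8 + [200.0] * 8] * 16)
        thr = rt.otsu_threshold(w)
        np.testing.assert_array_equal(w > thr, w == 200.0)

    def test_constant_window_gives_empty_foreground(self):
        w = np.full((20, 20), 7.0)
        thr = rt.otsu_threshold(w)
        assert not np.any(w > thr)


# ---------------------------------------------------------------------------
# particle detection / selection
# ---------------------------------------------------------------------------

class TestDetectSelect:
    def test_area_filter_is_strict(self):
        """A 3-px component is discarded, a 5-px one kept."""
        mask = np.zeros((20, 20), bool)
        mask[2, 2:5] = True           # 3 px: dropped
        mask[10, 10:15] = True        # 5 px: kept
        labels = rt.detect_particles(mask, min_area_px=3)
        kept = np.unique(labels[labels > 0])
        assert len(kept) == 1
        assert np.count_nonzero(labels) == 5

    def test_diagonal_pixels_are_one_component(self):
        mask = np.zeros((10, 10), bool)
        mask[3, 3] = mask[4, 4] = True
        labels = rt.detect_particles(mask, min_area_px=0)
        assert labels.max() == 1
        labels = rt.detect_particles(mask, min_area_px=0, connectivity=4)
        assert labels.max() == 2

    def test_empty_mask_yields_nothing(self):
        labels = rt.detect_particles(np.zeros((10, 10), bool))
        assert labels.max() == 0

    def test_oversized_component_rejected(self):
        mask = np.ones((30, 30), bool)
        labels = rt.detect_particles(mask, min_area_px=3, max_area_px=100)
        assert labels.max() == 0

    def test_centrality_filter(self):
        labels = np.zeros((50, 50), int)
        labels[25 + 12, 25] = labels[25 + 12, 26] = 1   # 12 px off-center
        lab, n = rt.select_particle(labels, (25, 25), 10)
        assert lab is None and n == 0

    def test_largest_area_wins(self):
        labels = np.zeros((50, 50), int)
        labels[20:22, 20:23] = 1          # area 6
        labels[28:32, 25:30] = 2          # area 20
        lab, n = rt.select_particle(labels, (25, 25), 10)
        assert lab == 2 and n == 2

    def test_equal_area_tie_goes_to_nearest(self):
        labels = np.zeros((50, 50), int)
        labels[25, 33:35] = 1             # centroid 8.5 px from center
        labels[25, 26:28] = 2             # centroid 1.5 px from center
        lab, _ = rt.select_particle(labels, (25, 25), 10)
        assert lab == 2


# ---------------------------------------------------------------------------
# Feret
# ---------------------------------------------------------------------------

class TestFeret:
    @pytest.mark.parametrize("coords,expected", [
        ([[5, 5]], 0.0),
        ([[0, 0], [3, 4]], 5.0),
        ([[0, 0], [0, 7]], 7.0),
    ])
    def test_known_values(self, coords, expected):
        assert rt.feret_diameter(np.array(coords)) == pytest.approx(expected)

    def test_rasterized_disk_radius_10_gives_exactly_20(self):
        yy, xx = np.mgrid[-12:13, -12:13]
        coords = np.argwhere(yy ** 2 + xx ** 2 <= 100)
        assert rt.feret_diameter(coords) == 20.0

    def test_matches_all_pairs_brute_force_on_random_blobs(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = rng.integers(2, 40)
            coords = np.unique(rng.integers(0, 30, size=(n, 2)), axis=0)
            brute = max(math.dist(a, b)
                        for a, b in combinations(coords.tolist(), 2)) \
                if len(coords) > 1 else 0.0
            assert rt.feret_diameter(coords) == pytest.approx(brute,
                                                              abs=1e-12)

    def test_corner_convention_is_larger(self):
        coords = np.array([[0, 0], [0, 5]])
        centers = rt.feret_diameter(coords, "centers")
        corners = rt.feret_diameter(coords, "corners")
        assert corners == pytest.approx(math.hypot(6, 1))
        assert corners > centers


# ---------------------------------------------------------------------------
# track loop
# ---------------------------------------------------------------------------

class TestMeasureTrack:
    def test_noise_free_track_covers_event_support(self, wt_clean):
        """Measurements exist over the programmed event span and none after
        the event's end."""
        cfg, movie, events, measurements, _profiles = wt_clean
        for ev in events:
            track = measurements[measurements.track_id == ev.event_id]
            assert len(track) > 0
            t = track["t_s"].to_numpy()
            assert t.max() < ev.t_end_s
            # continuous coverage from the seed frame onwards
            assert t.min() <= ev.t_start_s + 2 * cfg.frame_interval_s
            assert len(track) >= 0.95 * (t.max() - t.min()) / 2.0

    def test_filters_hold_for_every_measurement(self, wt_noisy):
        params = rt.RoiParams()
        _cfg, _movie, _events, measurements, _profiles = wt_noisy
        assert (measurements["area_px"] > params.min_area_px).all()
        assert (measurements["center_distance_px"]
                <= params.max_center_dist_px).all()

    def test_track_count_matches_seed_count(self, wt_clean):
        _cfg, _movie, events, measurements, _profiles = wt_clean
        assert set(measurements["track_id"]) == {e.event_id for e in events}

    def test_empty_location_terminates_after_gap(self):
        cfg = fixed_phase_config(n_events=0, n_frames=40, shot_noise=False,
                                 read_noise_sd=0.0)
        movie, _ = sm.simulate(cfg)
        seed = rt.SeedTrack(track_id=0, first_frame=0, seed_yx=(128, 128))
        track = rt.measure_track(movie, seed)
        assert len(track) == 0

    def test_measurement_is_deterministic(self, wt_noisy):
        cfg, movie, events, measurements, _profiles = wt_noisy
        seeds = sm.seeds_from_events(events, cfg.frame_interval_s)
        again = rt.measure_tracks(movie, seeds)
        pd.testing.assert_frame_equal(measurements, again)

    def test_ring_diameter_recovered_within_optical_tolerance(self, wt_clean):
        """On noise-free renders, Feret × pixel size recovers the
        programmed diameter within ring thickness + 2 PSF sigma for
        resolvable rings."""
        cfg, movie, events, measurements, _profiles = wt_clean
        tol = cfg.ring_thickness_um + 2 * cfg.psf_sigma_um
        for ev in events:
            track = measurements[measurements.track_id == ev.event_id]
            for _, row in track.iterrows():
                d_true = sm.diameter_at_time(ev, row["t_s"], cfg)
                if d_true >= 3 * cfg.psf_sigma_um:
                    d_meas = row["feret_px"] * cfg.pixel_size_um
                    assert abs(d_meas - d_true) <= tol


def test_roi_params_validation():
    with pytest.raises(ValueError):
        rt.RoiParams(roi_size_px=15, max_center_dist_px=10).validate()
    with pytest.raises(ValueError):
        rt.RoiParams(gap_frames=0).validate()
    rt.RoiParams().validate()


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    pts=st.lists(st.tuples(st.integers(0, 30), st.integers(0, 30)),
                 min_size=1, max_size=25),
    dy=st.integers(-100, 100),
    dx=st.integers(-100, 100),
)
def test_feret_translation_invariant_and_matches_brute_force(pts, dy, dx):
    """Feret is invariant to translation and equals the all-pairs maximum."""
    coords = np.unique(np.array(pts), axis=0)
    base = rt.feret_diameter(coords)
    shifted = rt.feret_diameter(coords + np.array([dy, dx]))
    assert shifted == pytest.approx(base, abs=1e-9)
    if len(coords) > 1:
        brute = max(math.dist(a, b)
                    for a, b in combinations(coords.tolist(), 2))
    else:
        brute = 0.0
    assert base == pytest.approx(brute, abs=1e-12)
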