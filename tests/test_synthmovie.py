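"""Generator tests: kinetic sampling, diameter profiles, rendering, i/o."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from omegaquant import synthmovie as sm

from conftest import fixed_phase_config


def test_fixed_phase_durations_sum_to_lifetime():
    """100/100/150 s phases with zero sd give exactly 350-s lifetimes."""
    cfg = fixed_phase_config(n_events=5)
    events = sm.sample_events(cfg)
    assert len(events) == 5
    for ev in events:
        assert ev.lifetime_s == pytest.approx(350.0)
        assert ev.t_ramp_end_s - ev.t_start_s == pytest.approx(100.0)
        assert ev.t_max_diameter_s - ev.t_ramp_end_s == pytest.approx(100.0)
        assert not ev.has_stall


def test_wt_average_lifetime_configuration():
    """Phase means chosen to total the wild-type 330-s average, with zero
    sampling sd, yield identical 330-s lifetimes."""
    cfg = fixed_phase_config(n_events=6, t_constriction_s=(130.0, 0.0))
    lifetimes = [ev.lifetime_s for ev in sm.sample_events(cfg)]
    assert lifetimes == pytest.approx([330.0] * 6)


def test_zero_stall_duration_degenerates_to_wildtype():
    """A mutant preset with zero stall duration reproduces the wild-type
    timeline exactly under the same random draws."""
    wt = fixed_phase_config(rng_seed=7)
    mut = fixed_phase_config("hydrolysis_mutant", rng_seed=7,
                             stall_duration_s=(0.0, 0.0))
    for a, b in zip(sm.sample_events(wt), sm.sample_events(mut)):
        assert a.t_start_s == b.t_start_s
        assert a.t_end_s == b.t_end_s
        assert a.d_max_um == b.d_max_um
        assert not b.has_stall


def test_stall_duration_shifts_end_time_exactly():
    """Adding Δ to the programmed stall duration lengthens every event by
    exactly Δ, all other draws held fixed."""
    base = fixed_phase_config("hydrolysis_mutant", n_frames=400, rng_seed=5,
                              stall_duration_s=(150.0, 0.0))
    longer = fixed_phase_config("hydrolysis_mutant", n_frames=400, rng_seed=5,
                                stall_duration_s=(250.0, 0.0))
    for a, b in zip(sm.sample_events(base), sm.sample_events(longer)):
        assert b.t_end_s - a.t_end_s == pytest.approx(100.0)
        assert a.t_stall_start_s == pytest.approx(b.t_stall_start_s)


def test_event_placement_respects_separation_or_errors():
    cfg = fixed_phase_config(n_events=8, image_shape=(512, 512))
    events = sm.sample_events(cfg)
    min_sep = 2 * cfg.d_max_range_um[1] / cfg.pixel_size_um
    for i, a in enumerate(events):
        for b in events[i + 1:]:
            dist = np.hypot(a.center_yx[0] - b.center_yx[0],
                            a.center_yx[1] - b.center_yx[1])
            assert dist >= min_sep
    crowded = fixed_phase_config(n_events=50, image_shape=(128, 128))
    with pytest.raises(sm.SimulationError, match="separation|margin"):
        sm.sample_events(crowded)


def test_events_must_fit_movie_unless_truncation_allowed():
    cfg = fixed_phase_config(n_frames=100)  # movie 200 s < 350 s lifetime
    with pytest.raises(sm.SimulationError, match="movie covers"):
        sm.sample_events(cfg)
    cfg.allow_truncation = True
    assert len(sm.sample_events(cfg)) == cfg.n_events


@pytest.fixture(scope="module")
def wt_event():
    cfg = fixed_phase_config(start_jitter_s=0.0)
    return cfg, sm.sample_events(cfg)[0]


class TestDiameterAtTime:
    def test_boundary_and_hold_values(self, wt_event):
        cfg, ev = wt_event
        assert sm.diameter_at_time(ev, ev.t_start_s, cfg) == pytest.approx(
            cfg.d_spot_um)
        mid_maturation = (ev.t_ramp_end_s + ev.t_max_diameter_s) / 2
        assert sm.diameter_at_time(ev, mid_maturation, cfg) == pytest.approx(
            ev.d_max_um)
        assert sm.diameter_at_time(ev, ev.t_end_s, cfg) == pytest.approx(0.0)

    def test_outside_support_raises(self, wt_event):
        cfg, ev = wt_event
        with pytest.raises(ValueError, match="outside"):
            sm.diameter_at_time(ev, ev.t_start_s - 1.0, cfg)
        with pytest.raises(ValueError, match="outside"):
            sm.diameter_at_time(ev, ev.t_end_s + 1.0, cfg)

    def test_mutant_plateau_holds_stall_diameter(self):
        cfg = fixed_phase_config("hydrolysis_mutant", n_frames=300,
                                 stall_duration_s=(200.0, 0.0))
        ev = sm.sample_events(cfg)[0]
        t_mid = (ev.t_stall_start_s + ev.t_stall_end_s) / 2
        assert sm.diameter_at_time(ev, t_mid, cfg) == pytest.approx(0.8)

    def test_continuity_and_zero_only_at_end(self):
        """On many random configurations the profile is continuous and
        strictly positive before the event's end."""
        rng = np.random.default_rng(42)
        for trial in range(40):
            genotype = ("wt", "hydrolysis_mutant")[trial % 2]
            cfg = sm.SimulationConfig.preset(
                genotype,
                n_events=5, image_shape=(512, 512), n_frames=1000,
                t_expansion_s=(rng.uniform(40, 150), rng.uniform(0, 20)),
                t_maturation_s=(rng.uniform(40, 150), rng.uniform(0, 20)),
                t_constriction_s=(rng.uniform(60, 200), rng.uniform(0, 20)),
                d_max_um=(rng.uniform(0.85, 1.4), rng.uniform(0, 0.2)),
                stall_duration_s=(rng.uniform(20, 150), 0.0),
                rng_seed=trial,
            )
            for ev in sm.sample_events(cfg):
                ts = np.linspace(ev.t_start_s, ev.t_end_s, 50)
                ds = [sm.diameter_at_time(ev, t, cfg) for t in ts]
                assert all(d > 0 for d in ds[:-1])
                assert ds[-1] == pytest.approx(0.0, abs=1e-9)
                # continuity: no jump larger than max slope × dt
                dt = ts[1] - ts[0]
                max_rate = 2.0 * cfg.d_max_range_um[1] * (
                    1 / cfg.frame_interval_s)
                assert np.max(np.abs(np.diff(ds))) <= max_rate * dt + 1e-9


class TestRendering:
    def test_radial_profile_peaks_at_ring_radius(self):
        """Noise-free thin-optics ring of diameter 1.0 µm at 0.1 µm pixels
        peaks at radius 5 px (brute-force argmax over the radial profile)."""
        cfg = sm.SimulationConfig(
            n_events=0, image_shape=(64, 64), n_frames=1,
            pixel_size_um=0.1, psf_sigma_um=0.02, ring_thickness_um=0.02,
            shot_noise=False, read_noise_sd=0.0, background_level=0.0)
        ev = sm.GroundTruthEvent(
            event_id=0, center_yx=(32, 32), t_start_s=0.0, t_ramp_end_s=0.0,
            t_max_diameter_s=10.0, t_end_s=20.0, d_max_um=1.0)
        frame = sm.render_movie([ev], cfg).channel("dfcp1")[0]
        yy, xx = np.mgrid[0:64, 0:64]
        r = np.round(np.hypot(yy - 32, xx - 32)).astype(int)
        radial = np.array([frame[r == k].mean() for k in range(20)])
        assert int(np.argmax(radial)) == 5

    def test_empty_field_is_background_only(self):
        cfg = fixed_phase_config(n_events=0, n_frames=5, shot_noise=False,
                                 read_noise_sd=0.0)
        movie, events = sm.simulate(cfg)
        assert events == []
        assert np.all(movie.intensities == cfg.background_level)

    def test_rendering_is_deterministic(self):
        cfg = fixed_phase_config(n_events=2, n_frames=30,
                                 allow_truncation=True)
        a, _ = sm.simulate(cfg)
        b, _ = sm.simulate(dataclasses.replace(cfg))
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_signal_zero_outside_event_supports(self):
        cfg = fixed_phase_config(n_events=2, start_jitter_s=0.0,
                                 shot_noise=False, read_noise_sd=0.0)
        movie, events = sm.simulate(cfg)
        signal = movie.intensities - cfg.background_level
        assert signal.min() >= 0
        # frames after every event has ended carry no signal
        last_end = max(ev.t_end_s for ev in events)
        first_dead = int(np.ceil(last_end / cfg.frame_interval_s))
        assert np.all(signal[first_dead:] == 0)


def test_write_read_round_trip(tmp_path, wt_clean):
    cfg, movie, events, _meas, _profiles = wt_clean
    paths = sm.write_simulation(movie, events, tmp_path, cfg)
    back = sm.read_movie(paths["movie"])
    np.testing.assert_array_equal(back.intensities, movie.intensities)
    assert back.channel_names == movie.channel_names
    assert back.pixel_size_um == movie.pixel_size_um
    seeds = pd.read_csv(paths["seeds"])
    assert len(seeds) == len(events)
    assert seeds["t_first_frame"].dtype.kind == "i"
    truth = pd.read_csv(paths["ground_truth"])
    assert len(truth) == len(events)
    assert truth["t_end_s"].dtype.kind == "f"


def test_invalid_configs_raise():
    with pytest.raises(sm.SimulationError):
        sm.SimulationConfig(pixel_size_um=-1).validate()
    with pytest.raises(sm.SimulationError):
        sm.SimulationConfig(p_recruit_cargo=1.5).validate()
    with pytest.raises(sm.SimulationError):
        sm.SimulationConfig(stall_diameter_um=1.2,
                            d_max_um=(1.0, 0.1)).validate()
    with pytest.raises(sm.SimulationError):
        sm.SimulationConfig.preset("nonsense")


def test_cell_field_truth_table_consistency():
    img, chans, truth = sm.simulate_cell_field(n_cells=4, rng_seed=1)
    assert img.shape[0] == len(chans) == 3
    assert len(truth) == 4
    assert (truth["n_cooccur_a"] <= truth["n_dots_a"]).all()
    assert (truth["n_cooccur_a"] <= truth["n_dots_b"]).all()
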