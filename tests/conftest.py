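"""Shared fixtures: small deterministic simulations reused across tests."""

import numpy as np
import pytest

from omegaquant import dynamics, ringtrack, synthmovie


def fixed_phase_config(genotype="wt", **overrides):
    """Config with the wild-type phase durations (100/100/150 s) fixed
    (zero sampling sd) so ground truth is exactly predictable."""
    kwargs = dict(
        n_events=3, image_shape=(256, 256), n_frames=200,
        t_expansion_s=(100.0, 0.0), t_maturation_s=(100.0, 0.0),
        t_constriction_s=(150.0, 0.0), d_max_um=(1.0, 0.0),
        start_jitter_s=10.0, rng_seed=1,
    )
    kwargs.update(overrides)
    return synthmovie.SimulationConfig.preset(genotype, **kwargs)


def run_pipeline(config, params=None):
    """simulate -> segment -> profiles, returning all intermediates."""
    movie, events = synthmovie.simulate(config)
    seeds = synthmovie.seeds_from_events(events, config.frame_interval_s)
    measurements = ringtrack.measure_tracks(movie, seeds, params)
    profiles = dynamics.build_profiles(
        measurements, config.pixel_size_um, config.frame_interval_s)
    return movie, events, measurements, profiles


@pytest.fixture(scope="session")
def wt_clean():
    """Noise-free wild-type run: 3 events, fixed 100/100/150 s phases."""
    cfg = fixed_phase_config(shot_noise=False, read_noise_sd=0.0)
    return cfg, *run_pipeline(cfg)


@pytest.fixture(scope="session")
def mutant_clean():
    """Noise-free hydrolysis-mutant run with a fixed 200-s stall."""
    cfg = fixed_phase_config("hydrolysis_mutant", n_frames=300,
                             stall_duration_s=(200.0, 0.0), rng_seed=2)
    cfg.shot_noise = False
    cfg.read_noise_sd = 0.0
    return cfg, *run_pipeline(cfg)


@pytest.fixture(scope="session")
def wt_noisy():
    """Wild-type run at the default noise level (SNR well above 5)."""
    cfg = fixed_phase_config(rng_seed=3)
    return cfg, *run_pipeline(cfg)
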