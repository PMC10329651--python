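"""Synthetic omegasome time-lapse generator.

Omegasomes are ring-shaped, PtdIns3P-positive ER subdomains on which
autophagosomes assemble.  In live imaging of fluorescently tagged DFCP1 they
appear as a diffraction-limited spot that expands into a ring of 0.5-1.5 µm
diameter, holds its maximum size while the phagophore matures, and then
constricts back to a spot before disappearing.  Cells expressing ATPase-dead
DFCP1 mutants constrict abnormally: the ring stalls near 0.8 µm for a
prolonged period before finally closing.

Because the original image data are not publicly deposited, this module
emulates the acquisitions: it samples per-event kinetic ground truth
(:func:`sample_events`), evaluates the programmed diameter profile
(:func:`diameter_at_time`), renders multi-channel movies with realistic shot
and read noise (:func:`render_movie`) and writes everything in open formats
(:func:`write_simulation`).  Every downstream stage of the package is
validated against this generator's exact ground truth.

Conventions
-----------
* Pixel coordinates are 0-based ``(row, col)``; pixel centers sit at integer
  coordinates and physical position = index × ``pixel_size_um``.
* The nominal event diameter is the *outer half-maximum* diameter of the
  rendered ring: the annulus centerline is drawn at
  ``d/2 − sqrt(2 ln 2) σ_r`` so that a thresholded Feret diameter (which
  reads the outer edge of the ring) recovers the programmed value.  In the
  near-delta-optics limit the centerline converges to ``d/2``.
* A ring narrower than twice the PSF sigma is rendered as a filled Gaussian
  spot (sub-resolution rings are indistinguishable from spots).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy.special import erf

__all__ = [
    "SimulationError",
    "SimulationConfig",
    "GroundTruthEvent",
    "MovieStack",
    "sample_events",
    "diameter_at_time",
    "render_movie",
    "simulate",
    "write_simulation",
    "read_movie",
    "read_ground_truth",
    "simulate_cell_field",
]

# Half-maximum offset of a Gaussian profile, in units of sigma.
_HWHM = math.sqrt(2.0 * math.log(2.0))

DFCP1_CHANNEL = "dfcp1"
CARGO_CHANNEL = "cargo"


class SimulationError(ValueError):
    """Raised for infeasible or inconsistent simulation configurations."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: Genotype presets.  Phase durations follow the measured wild-type kinetics
#: (expansion ≈ 100 s, maturation ≈ 100 s, constriction ≈ 150 s, 2-s frames).
#: ATPase-mutant presets stall at 0.8 µm; their stall-duration means are set
#: so the preset mean lifetimes are 500 s (ATP-binding mutant) and 450 s
#: (hydrolysis mutant).
GENOTYPE_PRESETS: dict[str, dict] = {
    "wt": {
        "stall_diameter_um": None,
        "stall_duration_s": (0.0, 0.0),
        "n_frames": 240,
    },
    "binding_mutant": {
        "stall_diameter_um": 0.8,
        "stall_duration_s": (150.0, 30.0),
        "n_frames": 360,
    },
    "hydrolysis_mutant": {
        "stall_diameter_um": 0.8,
        "stall_duration_s": (100.0, 30.0),
        "n_frames": 340,
    },
}


@dataclass
class SimulationConfig:
    """Parameters of a synthetic omegasome movie.

    Two-tuples are ``(mean, sd)`` of per-event normal sampling distributions;
    draws are floored at one frame interval (durations) or the stated range
    (diameters).
    """

    image_shape: tuple[int, int] = (256, 256)
    n_frames: int = 200
    frame_interval_s: float = 2.0
    pixel_size_um: float = 0.08
    n_events: int = 10
    genotype: str = "wt"

    # kinetics
    t_expansion_s: tuple[float, float] = (100.0, 15.0)
    t_maturation_s: tuple[float, float] = (100.0, 15.0)
    t_constriction_s: tuple[float, float] = (150.0, 20.0)
    start_jitter_s: float = 20.0
    d_spot_um: float = 0.2
    d_max_um: tuple[float, float] = (1.0, 0.25)
    d_max_range_um: tuple[float, float] = (0.5, 1.5)
    stall_diameter_um: Optional[float] = None
    stall_duration_s: tuple[float, float] = (0.0, 0.0)
    #: if set, per-event constriction time = d_max / rate (constant closure
    #: speed) instead of the ``t_constriction_s`` draw.
    constriction_rate_um_per_s: Optional[float] = None

    # cargo recruitment
    p_recruit_cargo: float = 0.8
    recruitment_delay_s: tuple[float, float] = (10.0, 5.0)

    # optics / rendering
    ring_thickness_um: float = 0.15
    psf_sigma_um: float = 0.1
    ring_amplitude: float = 400.0
    cargo_amplitude: float = 400.0
    background_level: float = 100.0
    shot_noise: bool = True
    read_noise_sd: float = 3.0

    rng_seed: int = 0
    #: when False (default) every event must finish within the movie;
    #: set True to study tracks truncated at movie end.
    allow_truncation: bool = False

    @classmethod
    def preset(cls, genotype: str, **overrides) -> "SimulationConfig":
        """Build a config from a genotype preset, with field overrides."""
        if genotype not in GENOTYPE_PRESETS:
            raise SimulationError(
                f"unknown genotype preset {genotype!r}; "
                f"choose from {sorted(GENOTYPE_PRESETS)}"
            )
        kwargs = dict(GENOTYPE_PRESETS[genotype])
        kwargs.update(overrides)
        return cls(genotype=genotype, **kwargs)

    def validate(self) -> None:
        if self.n_frames < 1 or self.n_events < 0:
            raise SimulationError("n_frames must be >=1 and n_events >=0")
        for name in ("frame_interval_s", "pixel_size_um", "d_spot_um",
                     "ring_thickness_um", "psf_sigma_um"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        for name in ("t_expansion_s", "t_maturation_s", "t_constriction_s",
                     "d_max_um"):
            if getattr(self, name)[0] <= 0:
                raise SimulationError(f"mean of {name} must be positive")
        if not 0.0 <= self.p_recruit_cargo <= 1.0:
            raise SimulationError("p_recruit_cargo must lie in [0, 1]")
        if self.stall_diameter_um is not None:
            if self.stall_diameter_um <= 0:
                raise SimulationError("stall_diameter_um must be positive")
            if self.stall_diameter_um >= self.d_max_um[0]:
                raise SimulationError(
                    "stall_diameter_um must be below the mean maximum diameter"
                )
        if self.read_noise_sd < 0 or self.background_level < 0:
            raise SimulationError("noise/background levels must be >= 0")

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s

    @property
    def channel_names(self) -> tuple[str, str]:
        return (DFCP1_CHANNEL, CARGO_CHANNEL)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthEvent:
    """Exact kinetic truth for one simulated omegasome.

    ``t_ramp_end_s`` is the first time the maximum diameter is reached (end
    of expansion); ``t_max_diameter_s`` is the constriction onset (end of
    maturation), i.e. the last time at maximum diameter — the operational
    "start of constriction".  Stall fields are ``None`` for events that
    constrict without a plateau.
    """

    event_id: int
    center_yx: tuple[int, int]
    t_start_s: float
    t_ramp_end_s: float
    t_max_diameter_s: float
    t_end_s: float
    d_max_um: float
    t_stall_start_s: Optional[float] = None
    t_stall_end_s: Optional[float] = None
    stall_diameter_um: Optional[float] = None
    cargo_recruited: bool = False
    t_cargo_s: Optional[float] = None

    @property
    def lifetime_s(self) -> float:
        return self.t_end_s - self.t_start_s

    @property
    def has_stall(self) -> bool:
        return self.t_stall_start_s is not None

    def completed_by(self, t: float) -> bool:
        """Whether the event fully constricts before time ``t``."""
        return self.t_end_s <= t


def sample_events(config: SimulationConfig,
                  rng: Optional[np.random.Generator] = None,
                  ) -> list[GroundTruthEvent]:
    """Sample per-event kinetics and well-separated spatial positions.

    The same random-variate sequence is consumed for every genotype (stall
    and recruitment draws are made even where inapplicable), so configs
    differing only in how draws are *used* see identical underlying draws.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.rng_seed).spawn(2)[0])
    n = config.n_events
    dt = config.frame_interval_s

    def _draw(dist, floor):
        mean, sd = dist
        return np.maximum(rng.normal(mean, sd, size=n), floor)

    t_start = rng.uniform(0.0, config.start_jitter_s, size=n)
    t_exp = _draw(config.t_expansion_s, dt)
    t_mat = _draw(config.t_maturation_s, dt)
    t_con = _draw(config.t_constriction_s, dt)
    lo, hi = config.d_max_range_um
    d_max = np.clip(rng.normal(*config.d_max_um, size=n), lo, hi)
    stall_dur = np.maximum(rng.normal(*config.stall_duration_s, size=n), 0.0)
    recruited = rng.uniform(size=n) < config.p_recruit_cargo
    delay = np.maximum(rng.normal(*config.recruitment_delay_s, size=n), 0.0)

    if config.constriction_rate_um_per_s is not None:
        if config.constriction_rate_um_per_s <= 0:
            raise SimulationError("constriction_rate_um_per_s must be positive")
        t_con = d_max / config.constriction_rate_um_per_s

    stall_d = config.stall_diameter_um
    if stall_d is not None:
        # a plateau closer than ~2 detection tolerances to the maximum is
        # indistinguishable from the maturation hold; stalling events keep
        # a resolvable drop before the plateau
        d_max = np.maximum(d_max, stall_d + 0.2)

    centers = _place_centers(config, rng)

    events: list[GroundTruthEvent] = []
    for i in range(n):
        ramp_end = t_start[i] + t_exp[i]
        con_start = ramp_end + t_mat[i]
        ev = GroundTruthEvent(
            event_id=i,
            center_yx=centers[i],
            t_start_s=float(t_start[i]),
            t_ramp_end_s=float(ramp_end),
            t_max_diameter_s=float(con_start),
            t_end_s=0.0,
            d_max_um=float(d_max[i]),
            cargo_recruited=bool(recruited[i]),
            t_cargo_s=float(t_start[i] + delay[i]) if recruited[i] else None,
        )
        if stall_d is not None and stall_dur[i] > 0:
            # split the falling time in proportion to the diameter covered,
            # i.e. a single closure speed before and after the plateau
            f1 = t_con[i] * (d_max[i] - stall_d) / d_max[i]
            f2 = t_con[i] * stall_d / d_max[i]
            ev.t_stall_start_s = float(con_start + f1)
            ev.t_stall_end_s = float(ev.t_stall_start_s + stall_dur[i])
            ev.stall_diameter_um = float(stall_d)
            ev.t_end_s = float(ev.t_stall_end_s + f2)
        else:
            ev.t_end_s = float(con_start + t_con[i])
        if not config.allow_truncation and ev.t_end_s > config.duration_s:
            raise SimulationError(
                f"event {i} ends at {ev.t_end_s:.1f} s but the movie covers "
                f"only {config.duration_s:.1f} s "
                f"(n_frames × frame_interval); lengthen the movie or set "
                f"allow_truncation=True"
            )
        events.append(ev)
    return events


def _place_centers(config: SimulationConfig,
                   rng: np.random.Generator) -> list[tuple[int, int]]:
    """Uniform rejection sampling with a minimum pairwise separation of
    2 × the largest expected diameter (events well separated by design)."""
    min_sep_px = 2.0 * config.d_max_range_um[1] / config.pixel_size_um
    margin = int(math.ceil(min_sep_px / 2.0)) + 2
    ny, nx = config.image_shape
    if config.n_events and (ny - 2 * margin <= 0 or nx - 2 * margin <= 0):
        raise SimulationError(
            f"image {config.image_shape} too small for the required border "
            f"margin of {margin} px (2 × max diameter separation rule)"
        )
    centers: list[tuple[int, int]] = []
    max_tries = 10_000
    for i in range(config.n_events):
        for _ in range(max_tries):
            y = int(rng.integers(margin, ny - margin))
            x = int(rng.integers(margin, nx - margin))
            if all(math.hypot(y - cy, x - cx) >= min_sep_px
                   for cy, cx in centers):
                centers.append((y, x))
                break
        else:
            raise SimulationError(
                f"could not place event {i}: {config.n_events} events with "
                f"minimum separation {min_sep_px:.0f} px do not fit in a "
                f"{ny}×{nx} field"
            )
    return centers


def diameter_at_time(event: GroundTruthEvent, t: float,
                     config: SimulationConfig) -> float:
    """Programmed ring diameter (µm) of ``event`` at absolute time ``t``.

    Piecewise linear: rise ``d_spot → d_max`` over expansion, hold over
    maturation, then a linear fall to zero — interrupted, for stalling
    events, by a constant plateau at the stall diameter.
    """
    if t < event.t_start_s or t > event.t_end_s:
        raise ValueError(
            f"t={t:.2f} s outside event support "
            f"[{event.t_start_s:.2f}, {event.t_end_s:.2f}] s")
    if t <= event.t_ramp_end_s:
        span = event.t_ramp_end_s - event.t_start_s
        if span <= 0:
            return event.d_max_um
        frac = (t - event.t_start_s) / span
        return config.d_spot_um + frac * (event.d_max_um - config.d_spot_um)
    if t <= event.t_max_diameter_s:
        return event.d_max_um
    if not event.has_stall:
        span = event.t_end_s - event.t_max_diameter_s
        return event.d_max_um * (event.t_end_s - t) / span
    if t <= event.t_stall_start_s:
        span = event.t_stall_start_s - event.t_max_diameter_s
        if span <= 0:
            return event.d_max_um
        frac = (t - event.t_max_diameter_s) / span
        return event.d_max_um + frac * (event.stall_diameter_um
                                        - event.d_max_um)
    if t <= event.t_stall_end_s:
        return event.stall_diameter_um
    span = event.t_end_s - event.t_stall_end_s
    return event.stall_diameter_um * (event.t_end_s - t) / span


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class MovieStack:
    """Multi-channel time-lapse with physical calibration (axes T×C×Y×X)."""

    intensities: np.ndarray
    channel_names: tuple[str, ...]
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self):
        if self.intensities.ndim != 4:
            raise ValueError("intensities must be a T×C×Y×X array")
        if self.intensities.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length must match axis C")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("calibration fields must be positive")

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[0]

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}") from None
        return self.intensities[:, idx]

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


def _ring_sigma_um(config: SimulationConfig) -> float:
    # annulus radial sigma: ring thickness (FWHM) convolved with the PSF
    thick_sigma = config.ring_thickness_um / (2.0 * _HWHM)
    return math.hypot(config.psf_sigma_um, thick_sigma)


def _paint_event(frame: np.ndarray, cargo: Optional[np.ndarray],
                 event: GroundTruthEvent, t: float,
                 config: SimulationConfig) -> None:
    d = diameter_at_time(event, t, config)
    if d <= 0:
        return
    px = config.pixel_size_um
    sigma_r = _ring_sigma_um(config)
    r_center = d / 2.0 - _HWHM * sigma_r  # outer half-max convention
    cy, cx = event.center_yx

    ext_um = d / 2.0 + 4.0 * sigma_r
    ext = int(math.ceil(ext_um / px)) + 1
    y0, y1 = max(cy - ext, 0), min(cy + ext + 1, frame.shape[0])
    x0, x1 = max(cx - ext, 0), min(cx + ext + 1, frame.shape[1])
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    r_um = np.hypot(yy - cy, xx - cx) * px

    if d < 2.0 * config.psf_sigma_um or r_center <= 0:
        sigma_spot = math.hypot(config.psf_sigma_um, d / 4.0)
        frame[y0:y1, x0:x1] += config.ring_amplitude * np.exp(
            -0.5 * (r_um / sigma_spot) ** 2)
    else:
        frame[y0:y1, x0:x1] += config.ring_amplitude * np.exp(
            -0.5 * ((r_um - r_center) / sigma_r) ** 2)

    if (cargo is not None and event.cargo_recruited
            and event.t_cargo_s is not None and t >= event.t_cargo_s):
        # cargo fills the lumen: a PSF-smoothed disk shrinking with the
        # ring.  Cargo is recruited from the spot stage onward, so a
        # sub-resolution lumen still images as a diffraction-limited
        # punctum: the footprint is floored at one PSF sigma.
        edge = config.psf_sigma_um
        r_lumen = max(r_center - sigma_r, edge)
        cargo[y0:y1, x0:x1] += config.cargo_amplitude * 0.5 * (
            1.0 + erf((r_lumen - r_um) / (math.sqrt(2.0) * edge)))


def render_movie(events: Sequence[GroundTruthEvent],
                 config: SimulationConfig) -> MovieStack:
    """Render DFCP1 + cargo channels with Poisson shot noise on
    signal + background, followed by Gaussian read noise; clipped at 0.

    Identical config (including seed) yields bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence(config.rng_seed).spawn(2)[1])
    ny, nx = config.image_shape
    movie = np.empty((config.n_frames, 2, ny, nx), dtype=np.float32)
    dt = config.frame_interval_s
    for i in range(config.n_frames):
        t = i * dt
        dfcp1 = np.full((ny, nx), config.background_level, dtype=np.float64)
        cargo = np.full((ny, nx), config.background_level, dtype=np.float64)
        for ev in events:
            # the event exists on [t_start, t_end); at t_end it has vanished
            if ev.t_start_s <= t < ev.t_end_s:
                _paint_event(dfcp1, cargo, ev, t, config)
        for c, chan in enumerate((dfcp1, cargo)):
            if config.shot_noise:
                chan = rng.poisson(np.clip(chan, 0, None)).astype(np.float64)
            if config.read_noise_sd > 0:
                chan = chan + rng.normal(0.0, config.read_noise_sd,
                                         size=chan.shape)
            movie[i, c] = np.clip(chan, 0, None)
    return MovieStack(movie, config.channel_names,
                      config.pixel_size_um, config.frame_interval_s)


def simulate(config: SimulationConfig
             ) -> tuple[MovieStack, list[GroundTruthEvent]]:
    """Sample events and render the movie in one deterministic call."""
    events = sample_events(config)
    return render_movie(events, config), events


# ---------------------------------------------------------------------------
# i/o
# ---------------------------------------------------------------------------

def events_to_frame(events: Sequence[GroundTruthEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        row = dataclasses.asdict(ev)
        cy, cx = row.pop("center_yx")
        row["center_y"], row["center_x"] = cy, cx
        rows.append(row)
    return pd.DataFrame(rows)


def seeds_from_events(events: Sequence[GroundTruthEvent],
                      frame_interval_s: float) -> pd.DataFrame:
    """Seed table standing in for manual track initiation: the first movie
    frame at/after each event's appearance, at the event center."""
    rows = [{
        "event_id": ev.event_id,
        "t_first_frame": int(math.ceil(ev.t_start_s / frame_interval_s
                                       - 1e-9)),
        "y": ev.center_yx[0],
        "x": ev.center_yx[1],
    } for ev in events]
    return pd.DataFrame(rows)


def write_simulation(movie: MovieStack, events: Sequence[GroundTruthEvent],
                     out_dir: str | Path,
                     config: Optional[SimulationConfig] = None) -> dict:
    """Write ``movie.tif`` (T×C×Y×X) with a JSON axes sidecar, plus
    ``ground_truth.csv``, ``seeds.csv`` and (when given) ``config.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "movie": out / "movie.tif",
        "sidecar": out / "movie.json",
        "ground_truth": out / "ground_truth.csv",
        "seeds": out / "seeds.csv",
    }
    tifffile.imwrite(paths["movie"], movie.intensities)
    paths["sidecar"].write_text(json.dumps({
        "axes": "TCYX",
        "channel_names": list(movie.channel_names),
        "pixel_size_um": movie.pixel_size_um,
        "frame_interval_s": movie.frame_interval_s,
    }, indent=2))
    events_to_frame(events).to_csv(paths["ground_truth"], index=False)
    seeds_from_events(events, movie.frame_interval_s).to_csv(
        paths["seeds"], index=False)
    if config is not None:
        paths["config"] = out / "config.json"
        paths["config"].write_text(
            json.dumps(dataclasses.asdict(config), indent=2))
    return paths


def read_movie(path: str | Path) -> MovieStack:
    """Read a movie written by :func:`write_simulation` (TIFF + sidecar)."""
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"axes sidecar {sidecar} not found next to {path}")
    meta = json.loads(sidecar.read_text())
    arr = tifffile.imread(path)
    arr = arr.reshape((-1, len(meta["channel_names"])) + arr.shape[-2:])
    return MovieStack(arr, tuple(meta["channel_names"]),
                      meta["pixel_size_um"], meta["frame_interval_s"])


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# fixed-cell dot fields (for puncta-analysis validation)
# ---------------------------------------------------------------------------

def simulate_cell_field(n_cells: int = 5,
                        image_shape: tuple[int, int] = (400, 400),
                        dots_per_cell_mean: float = 6.0,
                        co_occur_fraction: float = 0.5,
                        dot_amplitude: float = 250.0,
                        nucleus_amplitude: float = 400.0,
                        background_level: float = 50.0,
                        noise: bool = True,
                        rng_seed: int = 0,
                        ) -> tuple[np.ndarray, tuple[str, ...], pd.DataFrame]:
    """Render a fixed-cell field: a nuclear stain plus two puncta channels.

    Per cell, a Poisson number of channel-A dots is placed around the nucleus
    (each strictly nearer its own nucleus than any other, ≥6 px apart so
    counts are recoverable); a fraction of them co-occur with channel-B dots
    and additional independent B dots are added.  Returns
    ``(image C×Y×X, channel names, truth table)`` where the truth table has
    one row per cell with nucleus position and true per-channel dot counts.
    """
    rng = np.random.default_rng(rng_seed)
    ny, nx = image_shape
    # nuclei on a jittered grid, comfortably separated
    grid = int(math.ceil(math.sqrt(n_cells)))
    pitch_y, pitch_x = ny // grid, nx // grid
    nuclei = []
    for i in range(n_cells):
        gy, gx = divmod(i, grid)
        y = gy * pitch_y + pitch_y // 2 + int(rng.integers(-6, 7))
        x = gx * pitch_x + pitch_x // 2 + int(rng.integers(-6, 7))
        nuclei.append((y, x))
    nuclei_arr = np.array(nuclei, dtype=float)

    def _nearest(p):
        return int(np.argmin(np.hypot(nuclei_arr[:, 0] - p[0],
                                      nuclei_arr[:, 1] - p[1])))

    def _place_dots(count, cell_id, existing):
        placed = []
        tries = 0
        while len(placed) < count and tries < 5000:
            tries += 1
            r = rng.uniform(14, min(pitch_y, pitch_x) * 0.45)
            th = rng.uniform(0, 2 * math.pi)
            y = nuclei[cell_id][0] + r * math.sin(th)
            x = nuclei[cell_id][1] + r * math.cos(th)
            if not (4 <= y < ny - 4 and 4 <= x < nx - 4):
                continue
            if _nearest((y, x)) != cell_id:
                continue
            if any(math.hypot(y - py, x - px_) < 6.0
                   for py, px_ in existing + placed):
                continue
            placed.append((y, x))
        return placed

    chan_nuc = np.zeros(image_shape)
    chan_a = np.zeros(image_shape)
    chan_b = np.zeros(image_shape)
    yy, xx = np.mgrid[0:ny, 0:nx]

    def _blob(chan, y, x, sigma, amp):
        y0, y1 = max(int(y) - 4 * int(sigma) - 4, 0), min(
            int(y) + 4 * int(sigma) + 5, ny)
        x0, x1 = max(int(x) - 4 * int(sigma) - 4, 0), min(
            int(x) + 4 * int(sigma) + 5, nx)
        r2 = (yy[y0:y1, x0:x1] - y) ** 2 + (xx[y0:y1, x0:x1] - x) ** 2
        chan[y0:y1, x0:x1] += amp * np.exp(-0.5 * r2 / sigma ** 2)

    truth_rows = []
    all_dots: list[tuple[float, float]] = []
    for cid, (yn, xn) in enumerate(nuclei):
        _blob(chan_nuc, yn, xn, 6.0, nucleus_amplitude)
        n_a = int(rng.poisson(dots_per_cell_mean))
        a_dots = _place_dots(n_a, cid, all_dots)
        all_dots += a_dots
        n_b_extra = int(rng.poisson(dots_per_cell_mean * 0.5))
        b_extra = _place_dots(n_b_extra, cid, all_dots)
        all_dots += b_extra
        b_dots = list(b_extra)
        for y, x in a_dots:
            if rng.uniform() < co_occur_fraction:
                b_dots.append((y, x))
        for y, x in a_dots:
            _blob(chan_a, y, x, 1.5, dot_amplitude)
        for y, x in b_dots:
            _blob(chan_b, y, x, 1.5, dot_amplitude)
        truth_rows.append({
            "cell_id": cid, "nucleus_y": yn, "nucleus_x": xn,
            "n_dots_a": len(a_dots), "n_dots_b": len(b_dots),
            "n_cooccur_a": len(b_dots) - len(b_extra),
        })

    image = np.stack([chan_nuc, chan_a, chan_b]) + background_level
    if noise:
        image = rng.poisson(image).astype(np.float64)
        image = np.clip(image + rng.normal(0, 2.0, size=image.shape), 0, None)
    return (image.astype(np.float32), ("nuclei", "chan_a", "chan_b"),
            pd.DataFrame(truth_rows))
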