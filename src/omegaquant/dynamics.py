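"""Constriction dynamics: diameter profiles, phases, lifetimes, stalls.

Turns per-frame particle measurements into the quantities that describe an
omegasome's life cycle:

* a diameter-versus-time profile (Feret × pixel size, gap-interpolated and
  median-smoothed),
* phase boundaries — the earliest time at maximum diameter marks the start
  of constriction; disappearance marks full constriction,
* a per-track summary: lifetime, maximum diameter, phase durations,
  constriction success (final diameter < 0.5 µm), and stall metrics
  (a prolonged plateau during constriction, the ATPase-mutant signature),
* size-class trajectory ensembles (mean ± Student-t 95% CI), and
* the Spearman correlation between maximum diameter and track lifetime.
"""

from __future__ import annotations

import logging
import math
import warnings
from bisect import insort
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TrackProfile",
    "PhaseBoundaries",
    "TrackSummary",
    "TrajectoryEnsemble",
    "build_profile",
    "build_profiles",
    "segment_phases",
    "summarize_track",
    "summarize_tracks",
    "classify_by_max_diameter",
    "aggregate_trajectories",
    "correlate_size_lifetime",
    "lumen_resolved",
    "plot_ensembles",
    "plot_lifetimes",
]

log = logging.getLogger(__name__)

#: Diameter below which a constricting omegasome counts as closed (µm).
SUCCESS_THRESHOLD_UM = 0.5
#: Default maximum-diameter class edges (µm); half-open bins [lo, hi).
DEFAULT_SIZE_EDGES = (0.5, 0.8, 1.1, 1.4)


@dataclass
class TrackProfile:
    """Diameter time series of one track on its full frame grid."""

    track_id: int
    t_s: np.ndarray
    diameter_um: np.ndarray          # NaN where unmeasured/uninterpolated
    smoothed_diameter_um: np.ndarray
    condition: str = ""
    experiment_id: str = ""

    def __post_init__(self):
        if not (len(self.t_s) == len(self.diameter_um)
                == len(self.smoothed_diameter_um)):
            raise ValueError("profile arrays must share one length")
        if len(self.t_s) > 1 and not np.all(np.diff(self.t_s) > 0):
            raise ValueError("t_s must be strictly increasing")


@dataclass
class PhaseBoundaries:
    t_first_s: float
    t_ring_s: float   # smoothed diameter first exceeds ring threshold
    t_max_s: float    # earliest time at the smoothed maximum
    t_end_s: float    # disappearance (last measured frame)

    @property
    def expansion_s(self) -> float:
        return self.t_ring_s - self.t_first_s

    @property
    def maturation_s(self) -> float:
        return self.t_max_s - self.t_ring_s

    @property
    def constriction_s(self) -> float:
        return self.t_end_s - self.t_max_s


@dataclass
class TrackSummary:
    track_id: int
    lifetime_s: float
    d_max_um: float
    t_max_s: float
    expansion_duration_s: float
    maturation_duration_s: float
    constriction_duration_s: float
    final_diameter_um: float
    constricted_success: bool
    stall_detected: bool
    stall_diameter_um: Optional[float] = None
    stall_duration_s: Optional[float] = None
    size_class: str = ""
    condition: str = ""
    experiment_id: str = ""


@dataclass
class TrajectoryEnsemble:
    group: str
    t_s: np.ndarray
    mean_um: np.ndarray
    ci95_um: np.ndarray   # half-width
    n: np.ndarray


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def _fill_short_gaps(values: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate interior NaN runs of length ≤ max_gap."""
    out = values.copy()
    isnan = np.isnan(out)
    if not isnan.any():
        return out
    idx = np.arange(len(out))
    runs = []
    start = None
    for i, bad in enumerate(isnan):
        if bad and start is None:
            start = i
        elif not bad and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(out)))
    for s, e in runs:
        if s == 0 or e == len(out) or (e - s) > max_gap:
            continue
        out[s:e] = np.interp(idx[s:e], [s - 1, e], [out[s - 1], out[e]])
    return out


def _rolling_median(values: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling median, window truncated at the edges; NaNs are
    ignored within a window (a fully-NaN window stays NaN)."""
    half = window // 2
    out = np.full_like(values, np.nan)
    for i in range(len(values)):
        seg = values[max(i - half, 0):i + half + 1]
        seg = seg[~np.isnan(seg)]
        if seg.size:
            out[i] = np.median(seg)
    return out


def build_profile(measurements: pd.DataFrame, pixel_size_um: float,
                  frame_interval_s: float, gap_frames: int = 3,
                  smooth_window: int = 5, min_frames: int = 5,
                  condition: str = "", experiment_id: str = "",
                  ) -> Optional[TrackProfile]:
    """Diameter profile of one track's measurement table.

    Diameter = ``feret_px × pixel_size_um`` per measured frame; interior
    gaps of ≤ ``gap_frames`` frames are linearly interpolated; smoothing is
    a centered 5-frame rolling median (edges truncated).  Tracks with fewer
    than ``min_frames`` measured frames are skipped (returns ``None``).
    """
    if len(measurements) < min_frames:
        log.info("track %s skipped: only %d measured frames (<%d)",
                 measurements["track_id"].iloc[0] if len(measurements)
                 else "?", len(measurements), min_frames)
        return None
    meas = measurements.sort_values("frame")
    first, last = int(meas["frame"].iloc[0]), int(meas["frame"].iloc[-1])
    frames = np.arange(first, last + 1)
    diam = np.full(len(frames), np.nan)
    diam[meas["frame"].to_numpy() - first] = (
        meas["feret_px"].to_numpy() * pixel_size_um)
    diam = _fill_short_gaps(diam, gap_frames)
    return TrackProfile(
        track_id=int(meas["track_id"].iloc[0]),
        t_s=frames * frame_interval_s,
        diameter_um=diam,
        smoothed_diameter_um=_rolling_median(diam, smooth_window),
        condition=condition,
        experiment_id=experiment_id,
    )


def build_profiles(measurements: pd.DataFrame, pixel_size_um: float,
                   frame_interval_s: float, **kwargs) -> list[TrackProfile]:
    profiles = []
    for _, group in measurements.groupby("track_id"):
        p = build_profile(group, pixel_size_um, frame_interval_s, **kwargs)
        if p is not None:
            profiles.append(p)
    return profiles


# ---------------------------------------------------------------------------
# phases and summaries
# ---------------------------------------------------------------------------

def segment_phases(profile: TrackProfile,
                   ring_threshold_um: float = 0.3) -> PhaseBoundaries:
    """Phase boundaries of a profile.

    The earliest smoothed maximum starts constriction (a flat maximum must
    not defer it); the last measured frame is full constriction.  Maturation
    begins when the smoothed diameter first exceeds the ring-resolvability
    threshold (default 0.3 µm ≈ 3 × a typical PSF sigma); a track that never
    resolves as a ring has zero maturation and expands until ``t_max``.
    """
    d = profile.smoothed_diameter_um
    valid = ~np.isnan(d)
    if not valid.any():
        raise ValueError("profile has no measured frames")
    t = profile.t_s
    d_valid = np.where(valid, d, -np.inf)
    i_max = int(np.argmax(d_valid))          # first occurrence of the max
    above = np.flatnonzero(valid & (d > ring_threshold_um))
    i_ring = int(above[0]) if above.size else i_max
    i_ring = min(i_ring, i_max)
    i_first = int(np.flatnonzero(valid)[0])
    i_last = int(np.flatnonzero(valid)[-1])
    return PhaseBoundaries(t_first_s=float(t[i_first]),
                           t_ring_s=float(t[i_ring]),
                           t_max_s=float(t[i_max]),
                           t_end_s=float(t[i_last]))


def lumen_resolved(window: np.ndarray, mask: np.ndarray,
                   dip_fraction: float = 0.7) -> bool:
    """Alternative ring detector: does the particle show a lumen dip, i.e.
    center intensity below ``dip_fraction`` × the particle's peak?"""
    if not mask.any():
        return False
    coords = np.argwhere(mask)
    cy, cx = coords.mean(axis=0)
    center_val = window[int(round(cy)), int(round(cx))]
    return bool(center_val < dip_fraction * window[mask].max())


def _longest_band_run(values: np.ndarray, tol: float) -> tuple[int, int]:
    """Longest contiguous run where every value lies within ``tol`` of the
    run's own median.  Returns (start, stop) as a half-open index range."""
    n = len(values)
    best = (0, 0)
    i = 0
    while i < n:
        if math.isnan(values[i]):
            i += 1
            continue
        window: list[float] = []
        j = i
        while j < n and not math.isnan(values[j]):
            insort(window, values[j])
            m = len(window)
            med = (window[m // 2] if m % 2
                   else 0.5 * (window[m // 2 - 1] + window[m // 2]))
            if window[-1] - med >= tol or med - window[0] >= tol:
                break
            j += 1
        if j - i > best[1] - best[0]:
            best = (i, j)
        i += 1
    return best


def _fit_slopes(values: np.ndarray, t: np.ndarray, window: int) -> np.ndarray:
    """Centered least-squares slope over ``window`` frames (edge-truncated);
    NaN-tolerant."""
    half = window // 2
    out = np.full(len(values), np.nan)
    for i in range(len(values)):
        lo = max(i - half, 0)
        seg = values[lo:i + half + 1]
        ts = t[lo:i + half + 1]
        ok = ~np.isnan(seg)
        if ok.sum() >= 3:
            out[i] = np.polyfit(ts[ok], seg[ok], 1)[0]
    return out


def summarize_track(profile: TrackProfile,
                    boundaries: Optional[PhaseBoundaries] = None,
                    success_threshold_um: float = SUCCESS_THRESHOLD_UM,
                    stall_tolerance_um: float = 0.1,
                    stall_min_duration_s: float = 30.0,
                    stall_slope_window: int = 11,
                    stall_slope_tol_um_s: float = 0.0035,
                    stall_min_diameter_um: float = 0.45,
                    ring_threshold_um: float = 0.3) -> TrackSummary:
    """Lifetime, maximum diameter, success and stall metrics of one track.

    Stall detection scans the constriction limb — the smoothed profile
    after the track first departs its maximum plateau (first frame at/after
    ``t_max`` with diameter below ``d_max − stall_tolerance_um``; the hold
    at maximum is maturation, not a stall), restricted to frames with
    diameter above ``stall_min_diameter_um`` (below it the structure
    approaches the spot-size measurement floor, where the diameter readout
    plateaus trivially) — for the longest run whose
    values all lie within ``stall_tolerance_um`` of the run's median.
    Because such a band run necessarily annexes a slice of the constriction
    flanks (~tolerance / closure rate on each side), the interval is
    refined to the longest sub-run whose local slope (centered linear fit
    over ``stall_slope_window`` frames) stays within
    ``stall_slope_tol_um_s``.  A stall is reported when the refined flat
    core spans at least ``stall_min_duration_s``; the stall diameter is the
    core's median.  A steadily constricting track has no flat core and is
    never reported as stalled, however slowly it closes.
    """
    if boundaries is None:
        boundaries = segment_phases(profile, ring_threshold_um)
    t = profile.t_s
    d = profile.smoothed_diameter_um
    valid = ~np.isnan(d)
    i_last = int(np.flatnonzero(valid)[-1])
    final_d = float(d[i_last])
    d_max = float(np.nanmax(d))

    after = np.flatnonzero(valid & (t >= boundaries.t_max_s)
                           & (d < d_max - stall_tolerance_um))
    stall_detected = False
    stall_d = stall_dur = None
    if after.size:
        seg = d[after[0]:i_last + 1].copy()
        seg_t = t[after[0]:i_last + 1]
        seg[seg <= stall_min_diameter_um] = np.nan  # spot-floor frames
        s, e = _longest_band_run(seg, stall_tolerance_um)
        if e > s and (seg_t[e - 1] - seg_t[s]) >= stall_min_duration_s:
            slopes = _fit_slopes(seg, seg_t, stall_slope_window)
            flat = np.zeros(len(seg), dtype=bool)
            flat[s:e] = np.abs(slopes[s:e]) <= stall_slope_tol_um_s
            cs, ce = _longest_true_run(flat)
            if ce > cs and (seg_t[ce - 1] - seg_t[cs]
                            >= stall_min_duration_s):
                stall_detected = True
                stall_d = float(np.nanmedian(seg[cs:ce]))
                stall_dur = float(seg_t[ce - 1] - seg_t[cs])

    return TrackSummary(
        track_id=profile.track_id,
        lifetime_s=boundaries.t_end_s - boundaries.t_first_s,
        d_max_um=d_max,
        t_max_s=boundaries.t_max_s,
        expansion_duration_s=boundaries.expansion_s,
        maturation_duration_s=boundaries.maturation_s,
        constriction_duration_s=boundaries.constriction_s,
        final_diameter_um=final_d,
        constricted_success=bool(final_d < success_threshold_um),
        stall_detected=stall_detected,
        stall_diameter_um=stall_d,
        stall_duration_s=stall_dur,
        condition=profile.condition,
        experiment_id=profile.experiment_id,
    )


def _longest_true_run(mask: np.ndarray) -> tuple[int, int]:
    best = (0, 0)
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    if start is not None and len(mask) - start > best[1] - best[0]:
        best = (start, len(mask))
    return best


def summarize_tracks(profiles: Sequence[TrackProfile],
                     **kwargs) -> pd.DataFrame:
    rows = [vars(summarize_track(p, **kwargs)) for p in profiles]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# classification, ensembles, correlation
# ---------------------------------------------------------------------------

def classify_by_max_diameter(summaries: pd.DataFrame,
                             bin_edges: Sequence[float] = DEFAULT_SIZE_EDGES,
                             ) -> pd.DataFrame:
    """Assign each track to a half-open maximum-diameter class [lo, hi).

    A value exactly at an edge belongs to the upper bin; values below the
    lowest edge are labeled ``"sub-threshold"``.
    """
    edges = sorted(bin_edges)
    labels = ["sub-threshold"] + [
        f"[{edges[i]:g}, {edges[i+1]:g})" for i in range(len(edges) - 1)
    ] + [f"[{edges[-1]:g}, inf)"]
    out = summaries.copy()
    if len(out) == 0:
        out["size_class"] = pd.Series(dtype=str)
        return out
    idx = np.digitize(out["d_max_um"].to_numpy(), edges, right=False)
    out["size_class"] = [labels[i] for i in idx]
    return out


def aggregate_trajectories(profiles: Sequence[TrackProfile],
                           group_by: str = "condition",
                           alignment: str = "t_first",
                           min_tracks: int = 3,
                           use_smoothed: bool = False,
                           ) -> list[TrajectoryEnsemble]:
    """Per-group mean diameter trajectory with Student-t 95% CI.

    Profiles are aligned at their first measured frame (``"t_first"``) or at
    the maximum-diameter frame (``"t_max"``).  Timepoints with fewer than
    ``min_tracks`` contributing tracks are omitted; groups with fewer than
    ``min_tracks`` profiles are dropped with a warning.
    """
    if alignment not in ("t_first", "t_max"):
        raise ValueError("alignment must be 't_first' or 't_max'")
    groups: dict[str, list[TrackProfile]] = {}
    for p in profiles:
        groups.setdefault(getattr(p, group_by, "") or "all", []).append(p)
    ensembles = []
    for name, members in sorted(groups.items()):
        if len(members) < min_tracks:
            warnings.warn(f"group {name!r} has {len(members)} tracks "
                          f"(<{min_tracks}); omitted")
            continue
        aligned = []
        for p in members:
            d = p.smoothed_diameter_um if use_smoothed else p.diameter_um
            if alignment == "t_first":
                t0 = p.t_s[~np.isnan(d)][0] if (~np.isnan(d)).any() else 0.0
            else:
                t0 = p.t_s[int(np.nanargmax(p.smoothed_diameter_um))]
            aligned.append((p.t_s - t0, d))
        dt = np.min([np.min(np.diff(t)) for t, _ in aligned if len(t) > 1])
        lo = min(t[0] for t, _ in aligned)
        hi = max(t[-1] for t, _ in aligned)
        grid = np.arange(round(lo / dt), round(hi / dt) + 1) * dt
        stacks = np.full((len(aligned), len(grid)), np.nan)
        for k, (tk, dk) in enumerate(aligned):
            idx = np.round((tk - grid[0]) / dt).astype(int)
            stacks[k, idx] = dk
        n = np.sum(~np.isnan(stacks), axis=0)
        keep = n >= min_tracks
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(stacks, axis=0)
            sd = np.nanstd(stacks, axis=0, ddof=1)
        tcrit = np.where(n > 1, sps.t.ppf(0.975, np.maximum(n - 1, 1)), np.nan)
        ci = tcrit * sd / np.sqrt(np.maximum(n, 1))
        ensembles.append(TrajectoryEnsemble(
            group=name, t_s=grid[keep], mean_um=mean[keep],
            ci95_um=ci[keep], n=n[keep]))
    return ensembles


def correlate_size_lifetime(summaries: pd.DataFrame,
                            min_tracks: int = 5) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties) between each
    track's maximum diameter and its lifetime; two-sided p-value."""
    if len(summaries) < min_tracks:
        raise ValueError(
            f"need at least {min_tracks} tracks, got {len(summaries)}")
    d = summaries["d_max_um"].to_numpy(dtype=float)
    life = summaries["lifetime_s"].to_numpy(dtype=float)
    if np.all(d == d[0]) or np.all(life == life[0]):
        warnings.warn("constant variable: Spearman rho undefined")
        return float("nan"), float("nan")
    res = sps.spearmanr(d, life)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

def plot_ensembles(ensembles: Sequence[TrajectoryEnsemble], path) -> None:
    """Mean diameter vs time per group, with the 95% CI band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for ens in ensembles:
        line, = ax.plot(ens.t_s, ens.mean_um, label=f"{ens.group}")
        ax.fill_between(ens.t_s, ens.mean_um - ens.ci95_um,
                        ens.mean_um + ens.ci95_um, alpha=0.25,
                        color=line.get_color())
    ax.axhline(SUCCESS_THRESHOLD_UM, ls="--", c="gray", lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("diameter (µm)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_lifetimes(summaries: pd.DataFrame, path,
                   group_by: str = "condition") -> None:
    """Per-track lifetime dot plot, one column per group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    groups = list(summaries.groupby(group_by)) or [("all", summaries)]
    rng = np.random.default_rng(0)   # jitter only; cosmetic
    for i, (name, grp) in enumerate(groups):
        x = i + rng.uniform(-0.12, 0.12, len(grp))
        ax.plot(x, grp["lifetime_s"], "o", ms=4, alpha=0.6)
        ax.hlines(grp["lifetime_s"].mean(), i - 0.25, i + 0.25,
                  color="black")
    ax.set_xticks(range(len(groups)))
    ax.set_xticklabels([str(n) for n, _ in groups], rotation=30)
    ax.set_ylabel("omegasome lifetime (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
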