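"""Per-track omegasome segmentation and measurement.

Mirrors the manual-seed particle-tracking workflow used for omegasome
movies: around each seed point a square region of interest (ROI, default
50×50 px) is extracted at every frame; the ROI is thresholded with Otsu's
method; 8-connected particles larger than 3 px are kept; of the particles
whose centroid falls within 10 px of the ROI center, the largest is taken as
the omegasome; its mean intensity, area and Feret's diameter are recorded.
A track ends after a run of frames (default 3) with no surviving particle.

The Otsu threshold is computed over a 256-bin histogram spanning the ROI's
own intensity range; foreground is *strictly above* the threshold and tied
maxima resolve to the lowest threshold.  Feret's diameter is the maximum
pairwise distance between pixel **centers** by default (the outline/corner
convention, ~1 px larger, is available via ``convention="corners"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .synthmovie import MovieStack

__all__ = [
    "RoiParams",
    "SeedTrack",
    "ParticleMeasurement",
    "extract_roi",
    "otsu_threshold",
    "detect_particles",
    "select_particle",
    "feret_diameter",
    "segment_roi",
    "measure_track",
    "measure_tracks",
    "read_seeds",
    "write_measurements",
    "MEASUREMENT_COLUMNS",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)

MEASUREMENT_COLUMNS = [
    "track_id", "frame", "t_s", "mean_intensity", "area_px", "feret_px",
    "centroid_y", "centroid_x", "center_distance_px", "n_candidates",
]


@dataclass
class RoiParams:
    """Segmentation parameters (defaults follow the tracking protocol)."""

    roi_size_px: int = 50
    min_area_px: int = 3          # exclusive: particles must be *larger*
    #: degenerate-threshold guard: Otsu on a structure-free (noise-only)
    #: window splits the noise in half and the foreground percolates into a
    #: component spanning much of the ROI; any component larger than this is
    #: discarded.  None disables the guard.  Default: ROI area / 4.
    max_area_px: Optional[int] = None
    #: contrast gate against the same failure mode: a selected particle
    #: must have mean intensity ≥ window median + this many window MADs.
    #: A real fluorescent structure sits far above the local background;
    #: upper-tail noise clumps do not.  None disables the gate.
    min_contrast_mads: Optional[float] = 5.0
    max_center_dist_px: float = 10.0
    gap_frames: int = 3
    follow_centroid: bool = True
    connectivity: int = 8
    feret_convention: str = "centers"

    def effective_max_area(self) -> int:
        return (self.roi_size_px ** 2 // 4 if self.max_area_px is None
                else self.max_area_px)

    def validate(self) -> None:
        if self.roi_size_px <= 2 * self.max_center_dist_px:
            raise ValueError(
                "roi_size_px must exceed 2 × max_center_dist_px")
        if self.min_area_px < 0:
            raise ValueError("min_area_px must be >= 0")
        if self.gap_frames < 1:
            raise ValueError("gap_frames must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class SeedTrack:
    track_id: int
    first_frame: int
    seed_yx: tuple[float, float]
    channel: str = "dfcp1"


@dataclass
class ParticleMeasurement:
    track_id: int
    frame: int
    t_s: float
    mean_intensity: float
    area_px: int
    feret_px: float
    centroid_yx: tuple[float, float]
    center_distance_px: float
    n_candidates: int


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def extract_roi(frame: np.ndarray, seed_yx: Sequence[float],
                roi_size: int = 50
                ) -> tuple[np.ndarray, tuple[int, int]]:
    """Square window of side ``roi_size`` centered on the seed.

    Windows clipped at image borders keep their true (smaller) extent.
    Returns ``(window, (y_offset, x_offset))`` where the offset maps window
    indices back to image coordinates.
    """
    sy, sx = int(round(seed_yx[0])), int(round(seed_yx[1]))
    ny, nx = frame.shape
    if not (0 <= sy < ny and 0 <= sx < nx):
        raise ValueError(f"seed {seed_yx} outside {frame.shape} image")
    half = roi_size // 2
    y0, y1 = max(sy - half, 0), min(sy - half + roi_size, ny)
    x0, x1 = max(sx - half, 0), min(sx - half + roi_size, nx)
    return frame[y0:y1, x0:x1], (y0, x0)


def otsu_threshold(window: np.ndarray) -> float:
    """Otsu's threshold over a 256-bin histogram of the window's own range.

    Returns the bin edge maximizing between-class variance (lowest edge on
    ties).  Foreground is ``window > threshold``; for a constant window the
    constant itself is returned, so the foreground is empty (degenerate
    input, not an error).
    """
    w = np.asarray(window, dtype=np.float64).ravel()
    if w.size == 0:
        raise ValueError("empty window")
    lo, hi = w.min(), w.max()
    if lo == hi:
        return float(lo)
    counts, edges = np.histogram(w, bins=256, range=(lo, hi))
    # Between-class variance in bin-index units (an affine map of the bin
    # centers, so the argmax is unchanged):
    #   sigma_b(k) ∝ (N·s0 − c0·S)² / (c0·(N − c0))
    # with c0/s0 the cumulative count/first moment of bins 0..k.  Exact
    # integer arithmetic keeps the lowest-threshold tie-break immune to
    # floating-point rounding between algebraically equivalent forms.
    c = np.cumsum(counts)
    s = np.cumsum(counts * np.arange(256))
    n_total, s_total = int(c[-1]), int(s[-1])
    best_num, best_den, best_k = -1, 1, 0
    for k in range(255):
        c0 = int(c[k])
        if c0 == 0 or c0 == n_total:
            continue
        num = (n_total * int(s[k]) - c0 * s_total) ** 2
        den = c0 * (n_total - c0)
        if num * best_den > best_num * den:   # strict: first max wins
            best_num, best_den, best_k = num, den, k
    return float(edges[best_k + 1])


def detect_particles(mask: np.ndarray, min_area_px: int = 3,
                     connectivity: int = 8,
                     max_area_px: Optional[int] = None) -> np.ndarray:
    """Label connected components and zero out those with area ≤ min_area_px
    ("larger than" read strictly).  Components larger than ``max_area_px``
    (when given) are also dropped — they indicate a degenerate threshold on
    a structure-free window, not a particle.  Returns the pruned label
    image."""
    structure = _STRUCT8 if connectivity == 8 else None
    labels, n = ndimage.label(np.asarray(mask, dtype=bool),
                              structure=structure)
    if n == 0:
        return labels
    areas = np.bincount(labels.ravel())
    bad = areas <= min_area_px
    if max_area_px is not None:
        bad |= areas > max_area_px
    kill = np.flatnonzero(bad)
    if kill.size:
        labels[np.isin(labels, kill[kill > 0])] = 0
    return labels


def select_particle(labels: np.ndarray, roi_center_yx: Sequence[float],
                    max_center_dist: float = 10.0
                    ) -> tuple[Optional[int], int]:
    """Pick the omegasome among labeled candidates.

    Candidates are components whose centroid lies within
    ``max_center_dist`` of the ROI center; the largest-area one wins (ties:
    smaller center distance, then lower label).  Returns
    ``(label or None, n_candidates)``.
    """
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return None, 0
    centroids = ndimage.center_of_mass(np.ones_like(labels), labels, ids)
    cy, cx = roi_center_yx
    best = None  # (-area, distance, label)
    n_cand = 0
    areas = np.bincount(labels.ravel())
    for lab, (py, px) in zip(ids, centroids):
        dist = math.hypot(py - cy, px - cx)
        if dist > max_center_dist:
            continue
        n_cand += 1
        key = (-int(areas[lab]), dist, int(lab))
        if best is None or key < best:
            best = key
    return (None, 0) if best is None else (best[2], n_cand)


def feret_diameter(coords: np.ndarray, convention: str = "centers") -> float:
    """Maximum caliper (Feret) diameter of a pixel set, in pixels.

    ``coords`` is an (N, 2) array of pixel indices.  With the default
    ``"centers"`` convention distances are between pixel centers (a single
    pixel has Feret 0); ``"corners"`` measures across the pixel outlines
    (each pixel contributes its four corners), matching tools that report a
    one-pixel-larger diameter.
    """
    pts = np.asarray(coords, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("coords must be a non-empty (N, 2) array")
    if convention == "corners":
        off = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
        pts = (pts[:, None, :] + off[None, :, :]).reshape(-1, 2)
    elif convention != "centers":
        raise ValueError("convention must be 'centers' or 'corners'")
    pts = np.unique(pts, axis=0)
    if len(pts) == 1:
        return 0.0
    if len(pts) > 4:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:  # degenerate (collinear) point sets
            pass
    return max(math.dist(a, b) for a, b in combinations(pts, 2))


# ---------------------------------------------------------------------------
# per-frame segmentation and the track loop
# ---------------------------------------------------------------------------

def segment_roi(frame: np.ndarray, seed_yx: Sequence[float],
                params: RoiParams
                ) -> tuple[Optional[dict], Optional[np.ndarray],
                           tuple[int, int]]:
    """Segment one frame around a seed.

    Returns ``(result, mask, offset)``: ``result`` holds the selected
    particle's metrics in image coordinates (or ``None`` when no particle
    survives the area and centrality filters), ``mask`` is its boolean
    pixel mask within the ROI window, ``offset`` the window origin.
    """
    window, (oy, ox) = extract_roi(frame, seed_yx, params.roi_size_px)
    thr = otsu_threshold(window)
    labels = detect_particles(window > thr, params.min_area_px,
                              params.connectivity,
                              params.effective_max_area())
    center_local = (seed_yx[0] - oy, seed_yx[1] - ox)
    lab, n_cand = select_particle(labels, center_local,
                                  params.max_center_dist_px)
    if lab is None:
        return None, None, (oy, ox)
    mask = labels == lab
    if params.min_contrast_mads is not None:
        med = float(np.median(window))
        mad = float(np.median(np.abs(window - med)))
        if window[mask].mean() < med + params.min_contrast_mads * mad:
            return None, None, (oy, ox)
    coords = np.argwhere(mask)
    cy, cx = coords.mean(axis=0)
    result = {
        "mean_intensity": float(window[mask].mean()),
        "area_px": int(mask.sum()),
        "feret_px": feret_diameter(coords, params.feret_convention),
        "centroid_y": float(cy + oy),
        "centroid_x": float(cx + ox),
        "center_distance_px": math.hypot(cy - center_local[0],
                                         cx - center_local[1]),
        "n_candidates": n_cand,
    }
    return result, mask, (oy, ox)


def iter_track_frames(movie: MovieStack, seed: SeedTrack, params: RoiParams
                      ) -> Iterator[tuple[int, Optional[dict],
                                          Optional[np.ndarray],
                                          tuple[int, int]]]:
    """Walk a track frame by frame, yielding segmentation results until the
    track disappears (``gap_frames`` consecutive empty frames) or the movie
    ends.  When ``follow_centroid`` is set, the ROI recenters on the last
    measured centroid."""
    params.validate()
    channel = movie.channel(seed.channel)
    pos = tuple(seed.seed_yx)
    misses = 0
    for frame_idx in range(seed.first_frame, movie.n_frames):
        result, mask, offset = segment_roi(channel[frame_idx], pos, params)
        yield frame_idx, result, mask, offset
        if result is None:
            misses += 1
            if misses >= params.gap_frames:
                return
        else:
            misses = 0
            if params.follow_centroid:
                pos = (result["centroid_y"], result["centroid_x"])


def measure_track(movie: MovieStack, seed: SeedTrack,
                  params: Optional[RoiParams] = None) -> pd.DataFrame:
    """Measure one seeded track; frames with no surviving particle are
    simply absent from the output (missing measurements, not errors)."""
    params = params or RoiParams()
    rows = []
    for frame_idx, result, _mask, _off in iter_track_frames(
            movie, seed, params):
        if result is None:
            continue
        rows.append({"track_id": seed.track_id, "frame": frame_idx,
                     "t_s": frame_idx * movie.frame_interval_s, **result})
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def measure_tracks(movie: MovieStack, seeds: pd.DataFrame,
                   params: Optional[RoiParams] = None,
                   channel: str = "dfcp1") -> pd.DataFrame:
    """Measure every seed in a ``seeds.csv``-style table
    (columns ``event_id/track_id, t_first_frame, y, x``)."""
    params = params or RoiParams()
    id_col = "track_id" if "track_id" in seeds.columns else "event_id"
    tables = []
    for _, row in seeds.iterrows():
        seed = SeedTrack(track_id=int(row[id_col]),
                         first_frame=int(row["t_first_frame"]),
                         seed_yx=(float(row["y"]), float(row["x"])),
                         channel=channel)
        tables.append(measure_track(movie, seed, params))
    if not tables:
        return pd.DataFrame(columns=MEASUREMENT_COLUMNS)
    return pd.concat(tables, ignore_index=True)


def read_seeds(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_measurements(measurements: pd.DataFrame, path: str | Path) -> None:
    measurements.to_csv(path, index=False)
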