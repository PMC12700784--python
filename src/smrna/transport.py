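"""Directed-transport and spatial-distribution analysis.

Covers three measurements made on tracked single molecules:

* **kymographs** — intensity resampled along a user-drawn polyline over time
  (wide-reslice style: the maximum over a perpendicular width is taken, which
  keeps dim moving particles visible), in which a particle moving at speed
  ``v`` appears as a ridge of slope ``v``;
* **directed-run detection** — segmentation of tracks into motor-driven run
  events with per-event speeds from a least-squares fit of along-run
  projected position against time;
* **distance statistics** — per-spot Euclidean distances to the nucleus
  boundary and to the cell edge, from distance transforms of the mask
  boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import InputError, InsufficientDataError, ParameterError, RUN_COLUMNS
from .simulate import CellGeometry

__all__ = [
    "Kymograph",
    "DirectedRun",
    "extract_kymograph",
    "detect_runs",
    "detect_runs_table",
    "mean_transit_speed",
    "distances",
]

# Default run-detection thresholds: tuned to separate ~1.3 μm/s motor-driven
# runs from diffusion at D <= 0.2 μm²/s sampled at 10 frames/s.
MIN_RUN_FRAMES = 5
MIN_RUN_SPEED_UM_S = 0.5
MIN_STRAIGHTNESS = 0.8
#: Minimum mean cosine of the turning angle between consecutive steps.
#: A motor-driven run keeps direction (cos ~ 1); a random walk decorrelates
#: (cos ~ 0). Screens out short diffusive segments that are straight by chance;
#: 0.7 holds the diffusive false-positive rate below 5% at D = 0.05-0.2 μm²/s
#: while true runs sit near 1.
MIN_DIRECTION_CONSISTENCY = 0.7


@dataclass
class Kymograph:
    """Path-distance × time intensity matrix along a polyline."""

    matrix: np.ndarray          # (arc length px, n_frames)
    polyline_px: np.ndarray     # (k, 2) vertices as (x, y)
    width_px: int

    @property
    def n_positions(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class DirectedRun:
    """One directed-movement event within a track."""

    track_id: int
    t_start_s: float
    t_end_s: float
    speed_um_s: float
    direction: int          # +1 toward the path/run end, -1 reversed
    straightness: float     # net / path length, in [0, 1]


# ---------------------------------------------------------------------------
# Kymographs
# ---------------------------------------------------------------------------

def _resample_polyline(vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-arc-length sample points and unit normals along a polyline."""
    seg = np.diff(vertices, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = float(seg_len.sum())
    if total <= 0:
        raise InputError("polyline has zero length")
    n_pos = int(math.ceil(total))
    s_values = np.linspace(0.0, total, n_pos) if n_pos > 1 else np.array([0.0])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    points = np.empty((len(s_values), 2))
    normals = np.empty((len(s_values), 2))
    for k, s in enumerate(s_values):
        i = min(np.searchsorted(cum, s, side="right") - 1, len(seg) - 1)
        i = max(i, 0)
        frac = (s - cum[i]) / seg_len[i] if seg_len[i] > 0 else 0.0
        points[k] = vertices[i] + frac * seg[i]
        tangent = seg[i] / seg_len[i]
        normals[k] = (-tangent[1], tangent[0])
    return points, normals


def extract_kymograph(movie, polyline_px, width_px: int = 5,
                      aggregate: str = "max") -> Kymograph:
    """Resample a movie along a polyline into a kymograph.

    ``polyline_px`` is a sequence of (x, y) vertices in pixels. For each unit
    arc-length position and each frame, ``width_px`` samples are taken
    perpendicular to the path (bilinear interpolation) and aggregated with
    ``max`` (default; wide-reslice idiom) or ``mean``.
    """
    if width_px < 1 or width_px % 2 == 0:
        raise ParameterError("width_px must be an odd integer >= 1")
    if aggregate not in ("max", "mean"):
        raise ParameterError("aggregate must be 'max' or 'mean'")
    vertices = np.asarray(polyline_px, dtype=float)
    if vertices.ndim != 2 or vertices.shape[1] != 2 or len(vertices) < 2:
        raise InputError("polyline must be a (k >= 2, 2) array of (x, y)")
    n_frames, h, w = movie.data.shape
    if (vertices[:, 0] < 0).any() or (vertices[:, 0] > w).any() or (
        vertices[:, 1] < 0
    ).any() or (vertices[:, 1] > h).any():
        raise InputError("polyline lies outside the image")

    points, normals = _resample_polyline(vertices)
    offsets = np.arange(width_px) - width_px // 2
    # sample coordinates: (position, width) pairs of (x, y)
    sx = points[:, 0:1] + offsets[None, :] * normals[:, 0:1]
    sy = points[:, 1:2] + offsets[None, :] * normals[:, 1:2]
    # map_coordinates indexes arrays as (row, col) at pixel centres
    coords = np.stack([sy.ravel() - 0.5, sx.ravel() - 0.5])

    matrix = np.empty((len(points), n_frames), dtype=float)
    for t in range(n_frames):
        samples = ndimage.map_coordinates(
            movie.data[t].astype(float), coords, order=1, mode="nearest"
        ).reshape(len(points), width_px)
        matrix[:, t] = samples.max(axis=1) if aggregate == "max" else samples.mean(axis=1)
    return Kymograph(matrix, vertices, width_px)


# ---------------------------------------------------------------------------
# Directed runs
# ---------------------------------------------------------------------------

def _run_speed_and_direction(
    x: np.ndarray, y: np.ndarray, t: np.ndarray
) -> tuple[float, int]:
    """Speed from LSQ regression of along-run projected position vs time."""
    net = np.array([x[-1] - x[0], y[-1] - y[0]])
    norm = float(np.hypot(*net))
    if norm == 0:
        return 0.0, 1
    u = net / norm
    proj = (x - x[0]) * u[0] + (y - y[0]) * u[1]
    slope = float(np.polyfit(t, proj, 1)[0])
    return abs(slope), 1 if slope >= 0 else -1


def detect_runs(
    track: pd.DataFrame,
    min_frames: int = MIN_RUN_FRAMES,
    min_speed_um_s: float = MIN_RUN_SPEED_UM_S,
    min_straightness: float = MIN_STRAIGHTNESS,
    dt_s: float | None = None,
) -> list[DirectedRun]:
    """Segment one track into directed-movement events.

    Steps whose instantaneous speed reaches ``min_speed_um_s`` are classed as
    moving; maximal stretches of consecutive moving steps are candidate
    segments (pauses break them). A candidate becomes a run when it spans at
    least ``min_frames`` frames, its straightness (net over path length)
    reaches ``min_straightness``, its mean turning-angle cosine reaches
    ``MIN_DIRECTION_CONSISTENCY``, and its regression speed reaches
    ``min_speed_um_s``. Overlapping candidates are resolved longest-first,
    then earliest.

    ``track`` needs columns frame, x_um, y_um (single track_id).
    """
    if dt_s is None:
        dt_s = float(track.attrs.get("dt_s", 0.1))
    track = track.sort_values("frame")
    x = track["x_um"].to_numpy(dtype=float)
    y = track["y_um"].to_numpy(dtype=float)
    frames = track["frame"].to_numpy(dtype=int)
    track_id = int(track["track_id"].iloc[0]) if "track_id" in track else 0
    if len(x) < 2:
        return []

    step = np.hypot(np.diff(x), np.diff(y)) / (np.diff(frames) * dt_s)
    moving = step >= min_speed_um_s

    # maximal stretches of consecutive moving steps -> candidate segments
    candidates: list[tuple[int, int]] = []  # [start_idx, end_idx] inclusive, points
    i = 0
    while i < len(moving):
        if moving[i]:
            j = i
            while j + 1 < len(moving) and moving[j + 1]:
                j += 1
            candidates.append((i, j + 1))
            i = j + 1
        i += 1

    accepted: list[DirectedRun] = []
    taken: list[tuple[int, int]] = []
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0]))  # longest, then earliest
    for i0, i1 in candidates:
        if i1 - i0 + 1 < min_frames:
            continue
        if any(i0 <= e and s <= i1 for s, e in taken):
            continue
        xs, ys = x[i0 : i1 + 1], y[i0 : i1 + 1]
        ts = frames[i0 : i1 + 1] * dt_s
        net = float(np.hypot(xs[-1] - xs[0], ys[-1] - ys[0]))
        dx, dy = np.diff(xs), np.diff(ys)
        path = float(np.hypot(dx, dy).sum())
        straightness = net / path if path > 0 else 0.0
        speed, direction = _run_speed_and_direction(xs, ys, ts)
        if straightness < min_straightness or speed < min_speed_um_s:
            continue
        if len(dx) >= 2:
            norms = np.hypot(dx, dy)
            cosines = (dx[:-1] * dx[1:] + dy[:-1] * dy[1:]) / (
                norms[:-1] * norms[1:]
            )
            if float(np.mean(cosines)) < MIN_DIRECTION_CONSISTENCY:
                continue
        accepted.append(
            DirectedRun(track_id, float(ts[0]), float(ts[-1]), speed,
                        direction, straightness)
        )
        taken.append((i0, i1))
    accepted.sort(key=lambda r: r.t_start_s)
    return accepted


def detect_runs_table(
    tracks: pd.DataFrame,
    min_frames: int = MIN_RUN_FRAMES,
    min_speed_um_s: float = MIN_RUN_SPEED_UM_S,
    min_straightness: float = MIN_STRAIGHTNESS,
    dt_s: float | None = None,
) -> pd.DataFrame:
    """Run :func:`detect_runs` over every track of a linked-track table."""
    if dt_s is None:
        dt_s = float(tracks.attrs.get("dt_s", 0.1))
    rows = []
    if len(tracks):
        for _, grp in tracks.groupby("track_id", sort=True):
            for run in detect_runs(
                grp, min_frames, min_speed_um_s, min_straightness, dt_s
            ):
                rows.append(
                    (run.track_id, run.t_start_s, run.t_end_s, run.speed_um_s,
                     run.direction, run.straightness)
                )
    return pd.DataFrame(rows, columns=RUN_COLUMNS)


def mean_transit_speed(runs) -> tuple[float, float, int]:
    """Arithmetic mean and SD of per-run speeds; raises when empty."""
    if isinstance(runs, pd.DataFrame):
        speeds = runs["speed_um_s"].to_numpy(dtype=float)
    else:
        speeds = np.array([r.speed_um_s for r in runs], dtype=float)
    if len(speeds) == 0:
        raise InsufficientDataError("no directed runs to average")
    sd = float(np.std(speeds, ddof=1)) if len(speeds) > 1 else 0.0
    return float(np.mean(speeds)), sd, int(len(speeds))


# ---------------------------------------------------------------------------
# Distance statistics
# ---------------------------------------------------------------------------

def _boundary_distance_um(mask: np.ndarray, pixel_size_nm: float) -> np.ndarray:
    """Distance (μm) of every pixel centre to the nearest mask-boundary pixel."""
    boundary = mask & ~ndimage.binary_erosion(mask)
    if not boundary.any():
        raise InputError("mask has no boundary pixels")
    dist_px = ndimage.distance_transform_edt(~boundary)
    return dist_px * pixel_size_nm / 1000.0


def distances(
    spots: pd.DataFrame,
    geometry: CellGeometry,
    pixel_size_nm: float = 130.0,
) -> pd.DataFrame:
    """Per-spot distances to the nucleus boundary and to the cell edge.

    ``spots`` needs columns x_px, y_px (subpixel). Distances are bilinearly
    interpolated from Euclidean distance transforms of the mask boundaries
    and reported in μm. Spots outside the cell mask are flagged
    (``inside_cell = False``) and carry NaN distances.
    """
    if geometry.cell_mask.size == 0:
        raise InputError("empty geometry masks")
    d_nuc = _boundary_distance_um(geometry.nucleus_mask, pixel_size_nm)
    d_edge = _boundary_distance_um(geometry.cell_mask, pixel_size_nm)

    x = spots["x_px"].to_numpy(dtype=float)
    y = spots["y_px"].to_numpy(dtype=float)
    coords = np.stack([y - 0.5, x - 0.5])  # pixel-centre convention
    nuc = ndimage.map_coordinates(d_nuc, coords, order=1, mode="nearest")
    edge = ndimage.map_coordinates(d_edge, coords, order=1, mode="nearest")

    h, w = geometry.cell_mask.shape
    ii = np.clip(y.astype(int), 0, h - 1)
    jj = np.clip(x.astype(int), 0, w - 1)
    inside = geometry.cell_mask[ii, jj] & (x >= 0) & (x < w) & (y >= 0) & (y < h)

    out = pd.DataFrame({
        "x_px": x,
        "y_px": y,
        "dist_to_nucleus_um": np.where(inside, nuc, np.nan),
        "dist_to_edge_um": np.where(inside, edge, np.nan),
        "inside_cell": inside,
    })
    return out
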