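"""Ground-truthed simulation of single-molecule RNA imaging experiments.

This module generates the three kinds of synthetic data the analysis stages
consume, with known ground truth attached:

* **trajectories** of point emitters moving inside an elliptical cell — a
  mixture of a slow (optionally fully anchored) population and either a
  fast-diffusing or a motor-driven, directed population;
* **rendered movies** — diffraction-limited spots (integrated 2D Gaussian
  point-spread function) with Poisson shot noise and Gaussian read noise,
  emulating a widefield sCMOS acquisition at 130 nm/px and 10 frames/s;
* **two-channel fixed-cell scenes** for colocalization analysis, where a known
  fraction of channel-A spots has a jittered channel-B partner.

Shipped scene presets encode the study conditions: a translation-anchored
mRNA whose slow fraction collapses under puromycin (``notch2_*``), a
microtubule-transported mRNA with directed runs at 1.3–1.5 μm/s
(``map1b_*``), and an 85%-colocalized two-channel scene (``coloc_fixed``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import erf

from .core import InputError, Movie, ParameterError

__all__ = [
    "ImagingConfig",
    "CellGeometry",
    "KineticParams",
    "ScenePreset",
    "GroundTruthTrack",
    "PRESETS",
    "make_geometry",
    "simulate_tracks",
    "render_movie",
    "make_two_channel_scene",
    "tracks_to_table",
]

#: Brownian substeps per camera frame; keeps boundary reflection from
#: distorting the per-frame displacement distribution near the cell edge.
N_SUBSTEPS = 10

#: Mean pause duration for directed particles, in frames (geometric law).
PAUSE_MEAN_FRAMES = 5


@dataclass(frozen=True)
class ImagingConfig:
    """Camera and optics parameters of the emulated acquisition."""

    pixel_size_nm: float = 130.0
    frame_interval_s: float = 0.1
    n_frames: int = 250
    height_px: int = 256
    width_px: int = 256
    psf_sigma_nm: float = 169.0       # ~1.3 px: diffraction-limited GFP PSF
    photons_per_spot: float = 500.0
    bg_photons_per_px: float = 10.0
    read_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "pixel_size_nm", "frame_interval_s", "n_frames", "height_px",
            "width_px", "psf_sigma_nm",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        for name in ("photons_per_spot", "bg_photons_per_px", "read_noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_nm / self.pixel_size_nm


@dataclass(frozen=True)
class CellGeometry:
    """Binary cell and nucleus masks (nucleus strictly inside the cell)."""

    cell_mask: np.ndarray
    nucleus_mask: np.ndarray

    def __post_init__(self) -> None:
        cell = np.asarray(self.cell_mask, bool)
        nuc = np.asarray(self.nucleus_mask, bool)
        object.__setattr__(self, "cell_mask", cell)
        object.__setattr__(self, "nucleus_mask", nuc)
        if cell.shape != nuc.shape:
            raise InputError("cell and nucleus masks must have identical shapes")
        if not cell.any() or not nuc.any():
            raise InputError("masks must be nonempty")
        if (nuc & ~cell).any():
            raise InputError("nucleus mask must lie inside the cell mask")


@dataclass(frozen=True)
class KineticParams:
    """Motion-model parameters of the simulated mRNA population.

    A fraction ``F_slow`` of particles is slow — fully stationary when
    ``anchored`` is true (membrane-docked), otherwise diffusing at ``D_slow``.
    The remainder diffuses at ``D_fast``, or, when ``run_speed > 0``, undergoes
    directed transport toward the nearest cell-edge point with stochastic
    pauses and reversals.
    """

    D_fast: float = 2.0              # μm²/s
    D_slow: float = 0.05             # μm²/s
    F_slow: float = 0.5
    run_speed: float = 0.0           # μm/s
    run_duration_mean_s: float = 3.0
    pause_prob_per_step: float = 0.0
    reversal_prob_per_step: float = 0.0
    anchored: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.F_slow <= 1.0:
            raise ParameterError("F_slow must lie in [0, 1]")
        if self.D_slow < 0 or self.D_fast < 0 or self.run_speed < 0:
            raise ParameterError("diffusivities and run_speed must be >= 0")
        if self.D_slow > self.D_fast:
            raise ParameterError("D_slow must not exceed D_fast")
        for name in ("pause_prob_per_step", "reversal_prob_per_step"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ParameterError(f"{name} must be a probability")
        if self.run_duration_mean_s <= 0:
            raise ParameterError("run_duration_mean_s must be positive")


@dataclass(frozen=True)
class ScenePreset:
    """A named simulation scenario bundling kinetics and imaging settings."""

    name: str
    kinetics: KineticParams
    imaging: ImagingConfig
    coloc_fraction: float | None = None


PRESETS: dict[str, ScenePreset] = {
    # Translation-anchored perinuclear mRNA: a large static fraction that
    # collapses when translation is inhibited.
    "notch2_untreated": ScenePreset(
        "notch2_untreated",
        KineticParams(D_fast=2.0, D_slow=0.05, F_slow=0.7, anchored=True),
        ImagingConfig(),
    ),
    "notch2_puromycin": ScenePreset(
        "notch2_puromycin",
        KineticParams(D_fast=2.0, D_slow=0.05, F_slow=0.2, anchored=True),
        ImagingConfig(),
    ),
    # Motor-driven mRNA transported toward the cell edge; the preset describes
    # the directed subpopulation whose per-event speeds are measured.
    "map1b_untreated": ScenePreset(
        "map1b_untreated",
        KineticParams(
            D_fast=2.0, D_slow=0.05, F_slow=0.0, run_speed=1.3,
            run_duration_mean_s=3.0, pause_prob_per_step=0.05,
            reversal_prob_per_step=0.02,
        ),
        ImagingConfig(n_frames=60, height_px=128, width_px=128),
    ),
    "map1b_puromycin": ScenePreset(
        "map1b_puromycin",
        KineticParams(
            D_fast=2.0, D_slow=0.05, F_slow=0.0, run_speed=1.5,
            run_duration_mean_s=3.0, pause_prob_per_step=0.05,
            reversal_prob_per_step=0.02,
        ),
        ImagingConfig(n_frames=60, height_px=128, width_px=128),
    ),
    # Two-channel fixed-cell scene for colocalization benchmarking.
    "coloc_fixed": ScenePreset(
        "coloc_fixed",
        KineticParams(D_fast=0.0, D_slow=0.0, F_slow=1.0, anchored=True),
        ImagingConfig(n_frames=1, height_px=512, width_px=512),
        coloc_fraction=0.85,
    ),
}


@dataclass
class GroundTruthTrack:
    """True per-frame positions (μm) and motion states of one particle."""

    particle_id: int
    x_um: np.ndarray
    y_um: np.ndarray
    state: np.ndarray  # str array; one of the STATES values per frame

    STATES = ("free_fast", "free_slow", "anchored", "directed_run", "paused")

    @property
    def n_frames(self) -> int:
        return len(self.x_um)


def tracks_to_table(tracks: list[GroundTruthTrack]) -> pd.DataFrame:
    """Flatten ground-truth tracks to a (particle_id, frame, x, y, state) table."""
    rows = []
    for tr in tracks:
        for t in range(tr.n_frames):
            rows.append((tr.particle_id, t, tr.x_um[t], tr.y_um[t], tr.state[t]))
    return pd.DataFrame(rows, columns=["particle_id", "frame", "x_um", "y_um", "state"])


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def make_geometry(
    height_px: int,
    width_px: int,
    cell_axes: tuple[float, float],
    nucleus_axes: tuple[float, float],
    seed: int = 0,
    center_jitter_px: float = 0.0,
) -> CellGeometry:
    """Build an elliptical cell mask containing an elliptical nucleus mask.

    ``cell_axes`` and ``nucleus_axes`` are (semi-axis-x, semi-axis-y) in
    pixels. Both ellipses are centred at the image centre; the nucleus centre
    can be jittered by up to ``center_jitter_px`` (uniform, seeded).
    """
    ax_c, ay_c = cell_axes
    ax_n, ay_n = nucleus_axes
    if ax_n >= ax_c or ay_n >= ay_c:
        raise InputError("nucleus axes must be strictly smaller than cell axes")
    cx, cy = width_px / 2.0, height_px / 2.0
    if ax_c >= cx or ay_c >= cy:
        raise InputError("cell ellipse does not fit inside the image")
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-center_jitter_px, center_jitter_px, size=2)
    # centre of the nucleus, clamped so it stays inside the cell
    nx = cx + float(np.clip(jitter[0], -(ax_c - ax_n), ax_c - ax_n))
    ny = cy + float(np.clip(jitter[1], -(ay_c - ay_n), ay_c - ay_n))

    yy, xx = np.mgrid[0:height_px, 0:width_px]
    xc, yc = xx + 0.5, yy + 0.5  # pixel centres
    cell = ((xc - cx) / ax_c) ** 2 + ((yc - cy) / ay_c) ** 2 <= 1.0
    nuc = ((xc - nx) / ax_n) ** 2 + ((yc - ny) / ay_n) ** 2 <= 1.0
    nuc &= cell
    return CellGeometry(cell_mask=cell, nucleus_mask=nuc)


# ---------------------------------------------------------------------------
# Trajectory simulation
# ---------------------------------------------------------------------------

def _inside(geometry: CellGeometry | None, x_px: float, y_px: float) -> bool:
    if geometry is None:
        return True
    h, w = geometry.cell_mask.shape
    i, j = int(y_px), int(x_px)
    if not (0 <= i < h and 0 <= j < w):
        return False
    return bool(geometry.cell_mask[i, j])


def _sample_positions_in_mask(
    mask: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform continuous positions (px) inside a binary mask."""
    ii, jj = np.nonzero(mask)
    idx = rng.integers(0, len(ii), size=n)
    offs = rng.uniform(0.0, 1.0, size=(n, 2))
    x = jj[idx] + offs[:, 0]
    y = ii[idx] + offs[:, 1]
    return np.column_stack([x, y])


def _nearest_edge_point(
    geometry: CellGeometry, x_px: float, y_px: float
) -> tuple[float, float]:
    """Centre of the boundary pixel of the cell mask nearest to (x, y)."""
    from scipy import ndimage

    cell = geometry.cell_mask
    boundary = cell & ~ndimage.binary_erosion(cell)
    ii, jj = np.nonzero(boundary)
    d2 = (jj + 0.5 - x_px) ** 2 + (ii + 0.5 - y_px) ** 2
    k = int(np.argmin(d2))
    return jj[k] + 0.5, ii[k] + 0.5


def simulate_tracks(
    geometry: CellGeometry | None,
    kinetics: KineticParams,
    imaging: ImagingConfig,
    n_particles: int,
    seed: int = 0,
) -> list[GroundTruthTrack]:
    """Simulate ground-truth particle trajectories inside the cell.

    Brownian particles advance by ``N_SUBSTEPS`` Gaussian substeps per frame
    with per-axis SD sqrt(2 D dt_sub), reflected at the cell-mask edge (a
    substep whose endpoint leaves the mask is mirrored about its start; if the
    mirror also leaves the mask the particle stays put for that substep).
    Directed particles run along the straight line from their birth position
    to the nearest cell-edge point at ``run_speed``, pausing and reversing
    stochastically per frame, and anchor on arrival. With ``geometry=None``
    the boundary is disabled and particles start near the image centre.

    Returns one :class:`GroundTruthTrack` per particle, with positions in μm.
    """
    if n_particles < 1:
        raise ParameterError("n_particles must be >= 1")
    rng = np.random.default_rng(seed)
    px = imaging.pixel_size_um
    dt = imaging.frame_interval_s
    dt_sub = dt / N_SUBSTEPS
    n_frames = imaging.n_frames

    if geometry is not None:
        start_px = _sample_positions_in_mask(geometry.cell_mask, n_particles, rng)
    else:
        cx, cy = imaging.width_px / 2.0, imaging.height_px / 2.0
        start_px = np.tile([cx, cy], (n_particles, 1)).astype(float)

    slow = rng.random(n_particles) < kinetics.F_slow
    directed = (~slow) & (kinetics.run_speed > 0)

    stop_prob = 1.0 - math.exp(-dt / kinetics.run_duration_mean_s)
    tracks: list[GroundTruthTrack] = []
    for p in range(n_particles):
        x = np.empty(n_frames)
        y = np.empty(n_frames)
        state = np.empty(n_frames, dtype=object)
        pos = start_px[p].copy()  # px
        x[0], y[0] = pos * px
        if slow[p]:
            state[0] = "anchored" if kinetics.anchored else "free_slow"
            D = 0.0 if kinetics.anchored else kinetics.D_slow
            for t in range(1, n_frames):
                if D > 0:
                    pos = _brownian_frame(pos, D, dt_sub, px, geometry, rng)
                x[t], y[t] = pos * px
                state[t] = state[0]
        elif directed[p]:
            _simulate_directed(
                pos, kinetics, imaging, geometry, rng, stop_prob, x, y, state
            )
        else:
            state[0] = "free_fast"
            for t in range(1, n_frames):
                pos = _brownian_frame(pos, kinetics.D_fast, dt_sub, px, geometry, rng)
                x[t], y[t] = pos * px
                state[t] = "free_fast"
        tracks.append(GroundTruthTrack(p, x, y, state))
    return tracks


def _brownian_frame(
    pos_px: np.ndarray,
    D: float,
    dt_sub: float,
    px: float,
    geometry: CellGeometry | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance one camera frame of Brownian motion (positions in px)."""
    sd_px = math.sqrt(2.0 * D * dt_sub) / px
    pos = pos_px.copy()
    steps = rng.normal(0.0, sd_px, size=(N_SUBSTEPS, 2))
    for s in steps:
        cand = pos + s
        if _inside(geometry, cand[0], cand[1]):
            pos = cand
            continue
        mirror = pos - s
        if _inside(geometry, mirror[0], mirror[1]):
            pos = mirror
    return pos


def _simulate_directed(
    pos_px: np.ndarray,
    kinetics: KineticParams,
    imaging: ImagingConfig,
    geometry: CellGeometry | None,
    rng: np.random.Generator,
    stop_prob: float,
    x: np.ndarray,
    y: np.ndarray,
    state: np.ndarray,
) -> None:
    px = imaging.pixel_size_um
    dt = imaging.frame_interval_s
    n_frames = imaging.n_frames
    pos = pos_px.copy()

    if geometry is not None:
        tx, ty = _nearest_edge_point(geometry, pos[0], pos[1])
        direction = np.array([tx - pos[0], ty - pos[1]])
    else:
        direction = rng.normal(size=2)
    norm = np.hypot(*direction)
    direction = direction / norm if norm > 0 else np.array([1.0, 0.0])
    step_px = kinetics.run_speed * dt / px

    mode = "run"  # run | pause | done
    pause_left = 0
    x[0], y[0] = pos * px
    state[0] = "directed_run"
    for t in range(1, n_frames):
        if mode == "run":
            if rng.random() < kinetics.reversal_prob_per_step:
                direction = -direction
            if rng.random() < kinetics.pause_prob_per_step:
                mode = "pause"
                pause_left = 1 + rng.geometric(1.0 / PAUSE_MEAN_FRAMES)
            elif rng.random() < stop_prob:
                mode = "done"
        if mode == "pause":
            pause_left -= 1
            if pause_left <= 0:
                mode = "run"
            x[t], y[t] = pos * px
            state[t] = "paused"
            continue
        if mode == "done":
            x[t], y[t] = pos * px
            state[t] = "anchored"
            continue
        cand = pos + direction * step_px
        if not _inside(geometry, cand[0], cand[1]):
            mode = "done"  # reached the cell edge
            x[t], y[t] = pos * px
            state[t] = "anchored"
            continue
        pos = cand
        x[t], y[t] = pos * px
        state[t] = "directed_run"


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _add_spots(
    image: np.ndarray,
    xs_px: np.ndarray,
    ys_px: np.ndarray,
    photons: float,
    sigma_px: float,
) -> None:
    """Accumulate integrated-Gaussian emitters into an expected-photon image."""
    h, w = image.shape
    half = int(math.ceil(4.0 * sigma_px)) + 1
    s = sigma_px * math.sqrt(2.0)
    for x0, y0 in zip(xs_px, ys_px):
        j0, i0 = int(x0), int(y0)
        jl, jr = max(0, j0 - half), min(w, j0 + half + 1)
        il, ir = max(0, i0 - half), min(h, i0 + half + 1)
        if jl >= jr or il >= ir:
            continue
        jj = np.arange(jl, jr + 1, dtype=float)
        ii = np.arange(il, ir + 1, dtype=float)
        fx = 0.5 * erf((jj - x0) / s)
        fy = 0.5 * erf((ii - y0) / s)
        image[il:ir, jl:jr] += photons * np.outer(np.diff(fy), np.diff(fx))


def render_movie(
    tracks: list[GroundTruthTrack],
    imaging: ImagingConfig,
    seed: int = 0,
    noise: bool = True,
) -> Movie:
    """Render ground-truth tracks into a calibrated fluorescence movie.

    Each emitter contributes an integrated 2D Gaussian PSF of
    ``psf_sigma_nm`` SD; pixel values are Poisson(signal + background) plus
    Gaussian read noise, clipped at zero. With ``noise=False`` the expected
    photon image (signal + background) is returned instead.
    """
    rng = np.random.default_rng(seed)
    px = imaging.pixel_size_um
    h, w = imaging.height_px, imaging.width_px
    sigma_px = imaging.psf_sigma_px
    n_frames = imaging.n_frames

    for tr in tracks:
        xs, ys = tr.x_um / px, tr.y_um / px
        if (xs < 0).any() or (xs > w).any() or (ys < 0).any() or (ys > h).any():
            raise ParameterError("track positions must lie within image bounds")

    data = np.empty((n_frames, h, w), dtype=float)
    for t in range(n_frames):
        expected = np.full((h, w), float(imaging.bg_photons_per_px))
        xs = np.array([tr.x_um[t] / px for tr in tracks if t < tr.n_frames])
        ys = np.array([tr.y_um[t] / px for tr in tracks if t < tr.n_frames])
        if imaging.photons_per_spot > 0 and len(xs):
            _add_spots(expected, xs, ys, imaging.photons_per_spot, sigma_px)
        if noise:
            frame = rng.poisson(expected).astype(float)
            if imaging.read_noise_sd > 0:
                frame += rng.normal(0.0, imaging.read_noise_sd, size=(h, w))
            data[t] = np.clip(frame, 0.0, None)
        else:
            data[t] = expected
    return Movie(data, imaging.pixel_size_nm, imaging.frame_interval_s)


# ---------------------------------------------------------------------------
# Two-channel scenes
# ---------------------------------------------------------------------------

def make_two_channel_scene(
    n_spots: int,
    coloc_fraction: float,
    jitter_px: float,
    imaging: ImagingConfig,
    seed: int = 0,
) -> tuple[Movie, Movie, pd.DataFrame]:
    """Simulate a two-channel fixed-cell scene with known colocalization.

    A binomial(n_spots, coloc_fraction) subset of channel-A spots receives a
    channel-B partner displaced by isotropic Gaussian jitter of SD
    ``jitter_px``; the remaining spots of each channel are placed
    independently, uniformly inside the field (8 px margin). Both channels
    carry ``n_spots`` spots. Returns single-frame movies for A and B plus the
    ground-truth pair table (columns a_index, b_index, xa_px, ya_px, xb_px,
    yb_px).
    """
    if n_spots < 1:
        raise ParameterError("n_spots must be >= 1")
    if not 0.0 <= coloc_fraction <= 1.0:
        raise ParameterError("coloc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = imaging.height_px, imaging.width_px
    margin = 8.0

    def uniform(n: int) -> np.ndarray:
        return np.column_stack([
            rng.uniform(margin, w - margin, size=n),
            rng.uniform(margin, h - margin, size=n),
        ])

    a = uniform(n_spots)
    n_paired = int(rng.binomial(n_spots, coloc_fraction))
    partners = a[:n_paired] + rng.normal(0.0, jitter_px, size=(n_paired, 2))
    partners = np.clip(partners, 1.0, [w - 1.0, h - 1.0])
    b = np.vstack([partners, uniform(n_spots - n_paired)])

    pairs = pd.DataFrame({
        "a_index": np.arange(n_paired),
        "b_index": np.arange(n_paired),
        "xa_px": a[:n_paired, 0], "ya_px": a[:n_paired, 1],
        "xb_px": b[:n_paired, 0], "yb_px": b[:n_paired, 1],
    })

    frame_cfg = replace(imaging, n_frames=1)

    def render(points: np.ndarray, channel_seed: int) -> Movie:
        tracks = [
            GroundTruthTrack(
                k,
                np.array([points[k, 0] * imaging.pixel_size_um]),
                np.array([points[k, 1] * imaging.pixel_size_um]),
                np.array(["anchored"], dtype=object),
            )
            for k in range(len(points))
        ]
        return render_movie(tracks, frame_cfg, seed=channel_seed)

    movie_a = render(a, int(rng.integers(2**31)))
    movie_b = render(b, int(rng.integers(2**31)))
    return movie_a, movie_b, pairs
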