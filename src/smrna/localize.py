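"""Detection and subpixel localization of diffraction-limited spots.

The pipeline per frame is the standard single-molecule one: a
difference-of-Gaussians band-pass, thresholded 8-connected local-maximum
detection with close-candidate merging, then least-squares fitting of a
symmetric 2D Gaussian (amplitude, subpixel centre, width, offset) inside a
small window around each candidate. Failed fits are flagged, never raised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .core import InputError, LOCALIZATION_COLUMNS, Movie, ParameterError

__all__ = [
    "LocalizeParams",
    "Localization",
    "bandpass",
    "detect_spots",
    "fit_spot",
    "localize_frame",
    "localize_movie",
]

MERGE_RADIUS_PX = 3.0
SIGMA_BOUNDS_PX = (0.5, 4.0)


@dataclass(frozen=True)
class LocalizeParams:
    """Detection/fitting parameters (defaults suit a ~1.3 px PSF)."""

    sigma_small_px: float = 1.0
    sigma_large_px: float = 3.0
    k_sd: float = 4.0
    window_px: int = 7

    def __post_init__(self) -> None:
        if self.sigma_small_px <= 0 or self.sigma_large_px <= 0:
            raise ParameterError("filter sigmas must be positive")
        if self.sigma_small_px >= self.sigma_large_px:
            raise ParameterError("sigma_small_px must be < sigma_large_px")
        if self.k_sd <= 0:
            raise ParameterError("k_sd must be positive")
        if self.window_px < 3 or self.window_px % 2 == 0:
            raise ParameterError("window_px must be an odd integer >= 3")


@dataclass
class Localization:
    """One fitted spot; coordinates are subpixel, in pixels."""

    frame: int
    x_px: float
    y_px: float
    intensity: float
    sigma_px: float
    background: float
    fit_ok: bool


def bandpass(
    frame: np.ndarray, sigma_small_px: float = 1.0, sigma_large_px: float = 3.0
) -> np.ndarray:
    """Zero-mean difference-of-Gaussians band-pass of a single frame."""
    if sigma_small_px <= 0 or sigma_large_px <= 0:
        raise ParameterError("filter sigmas must be positive")
    if sigma_small_px >= sigma_large_px:
        raise ParameterError("sigma_small_px must be < sigma_large_px")
    img = np.asarray(frame, dtype=float)
    out = ndimage.gaussian_filter(img, sigma_small_px) - ndimage.gaussian_filter(
        img, sigma_large_px
    )
    return out - out.mean()


def detect_spots(filtered: np.ndarray, k_sd: float = 4.0) -> list[tuple[int, int]]:
    """Candidate spot pixels in a band-passed frame.

    Local maxima (8-connectivity) whose filtered value exceeds
    mean + ``k_sd``·SD of the frame; candidates closer than 3 px are merged,
    keeping the brighter. Returns (row, col) integer pixel positions.
    """
    if k_sd <= 0:
        raise ParameterError("k_sd must be positive")
    img = np.asarray(filtered, dtype=float)
    threshold = img.mean() + k_sd * img.std()
    is_max = img == ndimage.maximum_filter(img, size=3, mode="nearest")
    ii, jj = np.nonzero(is_max & (img > threshold))
    if len(ii) == 0:
        return []
    order = np.argsort(img[ii, jj])[::-1]  # brightest first
    kept: list[tuple[int, int]] = []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if all((i - i2) ** 2 + (j - j2) ** 2 >= MERGE_RADIUS_PX**2 for i2, j2 in kept):
            kept.append((i, j))
    kept.sort()
    return kept


def _gauss2d(params: np.ndarray, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    amp, x0, y0, sigma, off = params
    return amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sigma**2)) + off


def fit_spot(
    frame: np.ndarray, candidate: tuple[int, int], window_px: int = 7
) -> Localization:
    """Least-squares symmetric-Gaussian fit around one candidate pixel.

    ``candidate`` is (row, col). The fit is flagged not-ok (never raised) when
    the window leaves the frame, the optimizer fails, the fitted sigma falls
    outside [0.5, 4] px, or the centre leaves the window.
    """
    img = np.asarray(frame, dtype=float)
    h, w = img.shape
    i0, j0 = candidate
    half = window_px // 2
    bad = Localization(0, float(j0) + 0.5, float(i0) + 0.5, 0.0, 0.0, 0.0, False)
    if not (half <= i0 < h - half and half <= j0 < w - half):
        return bad
    win = img[i0 - half : i0 + half + 1, j0 - half : j0 + half + 1]
    yy, xx = np.mgrid[i0 - half : i0 + half + 1, j0 - half : j0 + half + 1]
    xx = xx + 0.5  # pixel centres
    yy = yy + 0.5
    off0 = float(win.min())
    amp0 = float(win.max() - off0)
    if amp0 <= 0:
        return bad
    p0 = np.array([amp0, j0 + 0.5, i0 + 0.5, 1.3, off0])

    def residual(p: np.ndarray) -> np.ndarray:
        return (_gauss2d(p, xx, yy) - win).ravel()

    try:
        res = optimize.least_squares(
            residual,
            p0,
            bounds=(
                [0.0, j0 + 0.5 - half, i0 + 0.5 - half, 0.1, -np.inf],
                [np.inf, j0 + 0.5 + half, i0 + 0.5 + half, 8.0, np.inf],
            ),
            method="trf",
            max_nfev=200,
        )
    except Exception:
        return bad
    amp, x0, y0, sigma, off = res.x
    ok = (
        res.success
        and SIGMA_BOUNDS_PX[0] <= sigma <= SIGMA_BOUNDS_PX[1]
        and abs(x0 - (j0 + 0.5)) < half
        and abs(y0 - (i0 + 0.5)) < half
        and amp > 0
    )
    return Localization(0, float(x0), float(y0), float(amp), float(sigma),
                        float(off), bool(ok))


def localize_frame(
    frame: np.ndarray, params: LocalizeParams = LocalizeParams(), frame_index: int = 0
) -> list[Localization]:
    filtered = bandpass(frame, params.sigma_small_px, params.sigma_large_px)
    out = []
    for cand in detect_spots(filtered, params.k_sd):
        loc = fit_spot(frame, cand, params.window_px)
        loc.frame = frame_index
        out.append(loc)
    return out


def localize_movie(
    movie: Movie, params: LocalizeParams = LocalizeParams()
) -> pd.DataFrame:
    """Localize every frame of a movie.

    Returns a LocalizationTable DataFrame (columns
    frame, x_px, y_px, intensity, sigma_px, background, fit_ok) containing
    only successful fits, sorted by (frame, y_px, x_px). The source pixel
    pitch and frame interval are attached under ``df.attrs``.
    """
    if movie.n_frames == 0 or movie.data.size == 0:
        raise InputError("movie is empty")
    rows = []
    for t in range(movie.n_frames):
        for loc in localize_frame(movie.data[t], params, frame_index=t):
            if loc.fit_ok:
                rows.append(
                    (loc.frame, loc.x_px, loc.y_px, loc.intensity, loc.sigma_px,
                     loc.background, loc.fit_ok)
                )
    table = pd.DataFrame(rows, columns=LOCALIZATION_COLUMNS)
    table = table.sort_values(["frame", "y_px", "x_px"], kind="mergesort")
    table = table.reset_index(drop=True)
    table.attrs["pixel_size_nm"] = movie.pixel_size_nm
    table.attrs["frame_interval_s"] = movie.frame_interval_s
    return table
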