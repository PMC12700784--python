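"""Shared containers, errors and I/O helpers.

The package works in two coordinate systems:

* **pixels** — continuous image coordinates; the origin sits at the corner of
  pixel (0, 0) and pixel index ``i`` spans the half-open interval ``[i, i+1)``.
* **micrometres** — physical coordinates obtained by multiplying pixel
  coordinates by the camera pixel pitch (``pixel_size_nm / 1000``).

All tables are pandas DataFrames with fixed column schemas (see the
``*_COLUMNS`` constants) so that every CSV written by one stage is readable by
the next.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "SmrnaError",
    "ParameterError",
    "InputError",
    "InsufficientDataError",
    "DesignError",
    "Movie",
    "derive_seed",
    "LOCALIZATION_COLUMNS",
    "DISPLACEMENT_COLUMNS",
    "TRACK_COLUMNS",
    "RUN_COLUMNS",
    "read_movie",
    "write_movie",
    "read_mask",
    "write_mask",
    "read_table",
    "write_table",
]


class SmrnaError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(SmrnaError, ValueError):
    """A parameter violates its documented constraint."""


class InputError(SmrnaError, ValueError):
    """An input object (movie, table, mask) is malformed or empty."""


class InsufficientDataError(SmrnaError):
    """Too few observations for the requested statistic."""


class DesignError(SmrnaError, ValueError):
    """A sequence-design request cannot be satisfied."""


LOCALIZATION_COLUMNS = [
    "frame", "x_px", "y_px", "intensity", "sigma_px", "background", "fit_ok",
]
DISPLACEMENT_COLUMNS = ["frame", "x0_um", "y0_um", "x1_um", "y1_um", "r_um"]
TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um"]
RUN_COLUMNS = [
    "track_id", "t_start_s", "t_end_s", "speed_um_s", "direction", "straightness",
]


@dataclass
class Movie:
    """A time-lapse image stack with physical calibration.

    Attributes
    ----------
    data
        Array of shape (T, H, W); photon counts (float) or camera counts
        (uint16).
    pixel_size_nm
        Camera pixel pitch in nanometres.
    frame_interval_s
        Time between successive frames, in seconds.
    meta
        Free-form metadata (preset name, seed, ...), persisted to the
        plain-text sidecar on save.
    """

    data: np.ndarray
    pixel_size_nm: float = 130.0
    frame_interval_s: float = 0.1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise InputError("movie data must be a (T, H, W) array")
        if self.pixel_size_nm <= 0 or self.frame_interval_s <= 0:
            raise ParameterError("pixel size and frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0


def derive_seed(global_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed below 2**31 from a global seed.

    The derivation hashes ``"<seed>:<stage>"`` so that adding, removing or
    reordering stages does not change any other stage's random stream.
    """
    digest = hashlib.sha256(f"{int(global_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def write_movie(path: str | Path, movie: Movie) -> None:
    """Write a movie as a multi-page 16-bit TIFF plus a plain-text sidecar."""
    path = Path(path)
    data = movie.data
    if data.dtype != np.uint16:
        data = np.clip(np.round(data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = path.with_suffix(path.suffix + ".meta")
    lines = {
        "pixel_size_nm": movie.pixel_size_nm,
        "frame_interval_s": movie.frame_interval_s,
        **movie.meta,
    }
    sidecar.write_text("".join(f"{k} = {v}\n" for k, v in lines.items()))


def read_movie(path: str | Path) -> Movie:
    """Read a multi-page TIFF movie; picks up the ``.meta`` sidecar if present."""
    path = Path(path)
    data = tifffile.imread(path)
    meta: dict = {}
    pixel_size_nm, frame_interval_s = 130.0, 0.1
    sidecar = path.with_suffix(path.suffix + ".meta")
    if sidecar.exists():
        for line in sidecar.read_text().splitlines():
            if "=" not in line:
                continue
            key, value = (part.strip() for part in line.split("=", 1))
            if key == "pixel_size_nm":
                pixel_size_nm = float(value)
            elif key == "frame_interval_s":
                frame_interval_s = float(value)
            else:
                meta[key] = value
    return Movie(np.asarray(data), pixel_size_nm, frame_interval_s, meta)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as a single-page 8-bit TIFF (0/255)."""
    tifffile.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path))) > 0


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(Path(path), index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
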