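"""Maximum-likelihood displacement-distribution analysis (SMdM).

Single-molecule displacement/diffusivity mapping infers diffusion
coefficients from the magnitudes ``r`` of single-frame displacements. For a
2D Brownian particle the displacement magnitude over a frame time ``Δt`` is
Rayleigh-distributed,

    P(r) = (2r / a) exp(-r² / a) + b·r,        a = 4·D·Δt,

where the ``b·r`` term absorbs a spatially uniform background of false pairs.
A two-component variant mixes two Rayleigh terms with weights ``F1`` and
``1 − F1`` (scales ``a1 = 4·D1·Δt``, ``a2 = 4·D2·Δt``) plus the same
background term, separating a slow/anchored population from a fast one.

Because displacement pairing is truncated at a search radius ``r_max``, the
densities above are renormalized over the observable support (0, r_max]:
the single-component normalizer is ``(1 − exp(−r_max²/a)) + b·r_max²/2``,
and the mixture normalizer is the corresponding weighted sum. This makes the
likelihood proper for any ``b ≥ 0``; an infinite ``r_max`` is permitted only
with ``b = 0``.

Fitting maximizes the truncated log-likelihood with bounded quasi-Newton
optimization and deterministic multistart (quantile-derived scale starts).
Spatially resolved maps fit each 2.5-px (325 nm at 130 nm/px) grid bin
separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .core import InputError, InsufficientDataError, ParameterError

__all__ = [
    "DisplacementSample",
    "SingleComponentFit",
    "TwoComponentFit",
    "DiffusivityMap",
    "loglik_single",
    "loglik_two",
    "fit_single",
    "fit_two",
    "map_diffusivity",
    "slow_fraction_per_cell",
]

D_BOUNDS_DEFAULT = (1e-4, 20.0)   # μm²/s
B_MAX = 100.0                     # background slope upper bound, per μm²
N_MIN_SINGLE = 30
N_MIN_TWO = 200
DEGENERATE_RATIO = 1.5
#: Minimum 2·ΔlogL of the mixture over the single-component fit for the two
#: components to count as resolved (a likelihood-ratio screen; the mixture
#: adds two parameters, and below this the weight F1 is meaningless).
MIN_LR_RESOLVED = 6.0
DEFAULT_BIN_SIZE_PX = 2.5


@dataclass(frozen=True)
class DisplacementSample:
    """Pooled displacement magnitudes with their frame time and truncation.

    ``r_um`` are single-frame displacement magnitudes in μm, all within
    (0, r_max_um]; ``dt_s`` is the frame time over which they were measured.
    """

    r_um: np.ndarray
    dt_s: float = 0.1
    r_max_um: float = np.inf

    def __post_init__(self) -> None:
        r = np.asarray(self.r_um, dtype=float).ravel()
        object.__setattr__(self, "r_um", r)
        if self.dt_s <= 0:
            raise ParameterError("dt_s must be positive")
        if self.r_max_um <= 0:
            raise ParameterError("r_max_um must be positive")
        if len(r) and (r <= 0).any():
            raise InputError("displacements must be strictly positive")
        if len(r) and (r > self.r_max_um).any():
            raise InputError("displacements exceed the truncation radius r_max")

    @classmethod
    def from_displacements(cls, disp: pd.DataFrame) -> "DisplacementSample":
        """Build a sample from a ``pair_displacements`` output table."""
        return cls(
            disp["r_um"].to_numpy(),
            dt_s=float(disp.attrs.get("dt_s", 0.1)),
            r_max_um=float(disp.attrs.get("r_max_um", np.inf)),
        )

    @property
    def n(self) -> int:
        return len(self.r_um)


@dataclass(frozen=True)
class SingleComponentFit:
    D: float          # μm²/s
    a: float          # = 4 D dt, μm²
    b: float          # background slope, per μm²
    logL: float
    n: int
    dt_s: float


@dataclass(frozen=True)
class TwoComponentFit:
    F1: float         # slow fraction
    D1: float         # μm²/s, D1 <= D2
    D2: float
    a1: float
    a2: float
    b: float
    logL: float
    n: int
    dt_s: float
    degenerate: bool  # flagged when D2/D1 < 1.5 (components unresolved)


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------

def _check_b_rmax(b: float, r_max: float) -> None:
    if b < 0:
        raise ParameterError("b must be >= 0")
    if not np.isfinite(r_max) and b > 0:
        raise ParameterError("b > 0 requires a finite truncation radius r_max")


def _rayleigh_norm(a: float, r_max: float) -> float:
    """∫₀^rmax (2r/a) e^{−r²/a} dr."""
    if not np.isfinite(r_max):
        return 1.0
    return -math.expm1(-r_max**2 / a)


def loglik_single(D: float, b: float, sample: DisplacementSample) -> float:
    """Truncated single-component log-likelihood at (D, b)."""
    if D <= 0:
        raise ParameterError("D must be positive")
    _check_b_rmax(b, sample.r_max_um)
    a = 4.0 * D * sample.dt_s
    r = sample.r_um
    dens = (2.0 * r / a) * np.exp(-(r**2) / a) + b * r
    norm = _rayleigh_norm(a, sample.r_max_um)
    if np.isfinite(sample.r_max_um):
        norm += b * sample.r_max_um**2 / 2.0
    # underflowed densities (r far beyond the Rayleigh scale with b = 0) are
    # clipped so the optimizer sees a finite, strongly penalized value
    return float(np.sum(np.log(np.clip(dens, 1e-300, None)))
                 - sample.n * math.log(norm))


def loglik_two(
    F1: float, D1: float, D2: float, b: float, sample: DisplacementSample
) -> float:
    """Truncated two-component mixture log-likelihood."""
    if D1 <= 0 or D2 <= 0:
        raise ParameterError("diffusivities must be positive")
    if not 0.0 <= F1 <= 1.0:
        raise ParameterError("F1 must lie in [0, 1]")
    _check_b_rmax(b, sample.r_max_um)
    a1 = 4.0 * D1 * sample.dt_s
    a2 = 4.0 * D2 * sample.dt_s
    r = sample.r_um
    dens = (
        F1 * (2.0 * r / a1) * np.exp(-(r**2) / a1)
        + (1.0 - F1) * (2.0 * r / a2) * np.exp(-(r**2) / a2)
        + b * r
    )
    norm = F1 * _rayleigh_norm(a1, sample.r_max_um) + (1.0 - F1) * _rayleigh_norm(
        a2, sample.r_max_um
    )
    if np.isfinite(sample.r_max_um):
        norm += b * sample.r_max_um**2 / 2.0
    return float(np.sum(np.log(np.clip(dens, 1e-300, None)))
                 - sample.n * math.log(norm))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _quantile_scales(sample: DisplacementSample) -> dict[str, float]:
    """Candidate Rayleigh scales a (μm²) derived from sample quantiles."""
    r2 = sample.r_um**2
    # For a pure Rayleigh, quantile q of r² equals −a·ln(1−q).
    return {
        "mean": float(np.mean(r2)),
        "q25": float(np.quantile(r2, 0.25) / -math.log(0.75)),
        "median": float(np.quantile(r2, 0.5) / math.log(2.0)),
        "q75": float(np.quantile(r2, 0.75) / -math.log(0.25)),
        "q10": float(np.quantile(r2, 0.10) / -math.log(0.90)),
        "q90": float(np.quantile(r2, 0.90) / -math.log(0.10)),
    }


def fit_single(
    sample: DisplacementSample,
    D_bounds: tuple[float, float] = D_BOUNDS_DEFAULT,
    multistart: int = 5,
    fit_background: bool = True,
    n_min: int = N_MIN_SINGLE,
) -> SingleComponentFit:
    """Fit the single-component model by truncated maximum likelihood.

    The scale is optimized in log space; with ``fit_background`` the
    background slope ``b`` is jointly optimized over [0, 100] per μm² from
    ``multistart`` deterministic starts (quantile-derived scales, b at 0 and
    a small positive value), otherwise ``b`` is fixed at 0 and a
    high-precision bounded scalar search is used.
    """
    if sample.n < n_min:
        raise InsufficientDataError(
            f"need at least {n_min} displacements, got {sample.n}"
        )
    dt = sample.dt_s
    lo, hi = D_bounds
    if not (0 < lo < hi):
        raise ParameterError("invalid D bounds")
    u_lo, u_hi = math.log(4 * lo * dt), math.log(4 * hi * dt)
    scales = _quantile_scales(sample)

    if not fit_background or not np.isfinite(sample.r_max_um):
        def neg(u: float) -> float:
            return -loglik_single(math.exp(u) / (4 * dt), 0.0, sample)

        res = optimize.minimize_scalar(
            neg, bounds=(u_lo, u_hi), method="bounded",
            options={"xatol": 1e-12, "maxiter": 500},
        )
        a = math.exp(res.x)
        return SingleComponentFit(a / (4 * dt), a, 0.0, -res.fun, sample.n, dt)

    def neg2(x: np.ndarray) -> float:
        return -loglik_single(math.exp(x[0]) / (4 * dt), x[1], sample)

    b_small = 1.0 / sample.r_max_um**2
    start_as = [scales["mean"], scales["q25"], scales["q75"], scales["median"],
                scales["mean"]]
    start_bs = [0.0, b_small, b_small, 0.0, b_small]
    best = None
    for a0, b0 in list(zip(start_as, start_bs))[:multistart]:
        u0 = min(max(math.log(max(a0, 1e-12)), u_lo), u_hi)
        res = optimize.minimize(
            neg2, np.array([u0, b0]), method="L-BFGS-B",
            bounds=[(u_lo, u_hi), (0.0, B_MAX)],
            options={"ftol": 1e-13, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    a = math.exp(best.x[0])
    return SingleComponentFit(
        a / (4 * dt), a, float(best.x[1]), -float(best.fun), sample.n, dt
    )


def fit_two(
    sample: DisplacementSample,
    multistart: int = 10,
    D_bounds: tuple[float, float] = D_BOUNDS_DEFAULT,
    fit_background: bool = True,
) -> TwoComponentFit:
    """Fit the two-component mixture by truncated maximum likelihood.

    Requires at least 200 displacements (mixture weights are unstable below
    that). Identifiability is enforced by relabelling so that ``D1 ≤ D2``;
    fits with ``D2/D1 < 1.5``, or whose log-likelihood improves on the
    single-component fit by less than ``MIN_LR_RESOLVED / 2``, are flagged
    degenerate (components unresolved), not raised.
    """
    if sample.n < N_MIN_TWO:
        raise InsufficientDataError(
            f"need at least {N_MIN_TWO} displacements for a mixture fit, "
            f"got {sample.n}"
        )
    dt = sample.dt_s
    lo, hi = D_bounds
    u_lo, u_hi = math.log(4 * lo * dt), math.log(4 * hi * dt)
    scales = _quantile_scales(sample)
    fit_b = fit_background and np.isfinite(sample.r_max_um)
    b_hi = B_MAX if fit_b else 0.0

    def neg(x: np.ndarray) -> float:
        f1 = x[0]
        d1 = math.exp(x[1]) / (4 * dt)
        d2 = math.exp(x[2]) / (4 * dt)
        return -loglik_two(f1, d1, d2, x[3], sample)

    def clamp(a0: float) -> float:
        return min(max(math.log(max(a0, 1e-12)), u_lo), u_hi)

    starts: list[tuple[float, float, float, float]] = []
    for f1 in (0.3, 0.5, 0.7):
        for lo_key, hi_key in (("q10", "q75"), ("q25", "q90")):
            starts.append((f1, clamp(scales[lo_key]), clamp(scales[hi_key]), 0.0))
    starts.append((0.5, clamp(scales["q10"] / 4), clamp(scales["q90"]), 0.0))
    starts.append((0.5, clamp(scales["q25"]), clamp(scales["q90"] * 4), 0.0))
    starts.append((0.9, clamp(scales["median"]), clamp(scales["q90"]), 0.0))
    starts.append((0.1, clamp(scales["q10"]), clamp(scales["median"]), 0.0))

    best = None
    for f1, u1, u2, b0 in starts[:multistart]:
        res = optimize.minimize(
            neg, np.array([f1, u1, u2, b0]), method="L-BFGS-B",
            bounds=[(1e-4, 1 - 1e-4), (u_lo, u_hi), (u_lo, u_hi), (0.0, b_hi)],
            options={"ftol": 1e-13, "gtol": 1e-10, "maxiter": 1000},
        )
        if best is None or res.fun < best.fun:
            best = res
    f1, u1, u2, b = best.x
    a1, a2 = math.exp(u1), math.exp(u2)
    if a1 > a2:  # relabel so component 1 is the slow one
        a1, a2 = a2, a1
        f1 = 1.0 - f1
    d1, d2 = a1 / (4 * dt), a2 / (4 * dt)
    logL = -float(best.fun)
    single = fit_single(
        sample, D_bounds=D_bounds, fit_background=fit_background, n_min=1
    )
    degenerate = (d2 / d1 < DEGENERATE_RATIO) or (
        2.0 * (logL - single.logL) < MIN_LR_RESOLVED
    )
    return TwoComponentFit(
        F1=float(f1), D1=d1, D2=d2, a1=a1, a2=a2, b=float(b),
        logL=logL, n=sample.n, dt_s=dt, degenerate=bool(degenerate),
    )


# ---------------------------------------------------------------------------
# Spatial mapping
# ---------------------------------------------------------------------------

@dataclass
class DiffusivityMap:
    """Per-bin apparent diffusivities on a square spatial grid.

    ``D_um2_s`` is NaN where a bin holds fewer than ``n_min`` displacements.
    The grid origin is image pixel (0, 0); bin (i, j) spans
    ``[j·s, (j+1)·s) × [i·s, (i+1)·s)`` pixels with ``s = bin_size_px``.
    """

    D_um2_s: np.ndarray
    n_per_bin: np.ndarray
    bin_size_px: float
    pixel_size_nm: float

    @property
    def bin_edge_nm(self) -> float:
        """Physical bin edge length (2.5 px × 130 nm/px = 325 nm by default)."""
        return self.bin_size_px * self.pixel_size_nm


def map_diffusivity(
    disp: pd.DataFrame,
    pixel_size_nm: float = 130.0,
    bin_size_px: float = DEFAULT_BIN_SIZE_PX,
    n_min: int = N_MIN_SINGLE,
    shape_px: tuple[int, int] | None = None,
) -> DiffusivityMap:
    """Spatially binned single-component diffusivity map.

    Each displacement is assigned to the grid bin containing the midpoint of
    its endpoints; bins holding at least ``n_min`` displacements are fitted
    with :func:`fit_single` (background included), the rest are NaN.
    ``shape_px`` optionally fixes the output grid to cover an (H, W) image.
    """
    if bin_size_px <= 0:
        raise ParameterError("bin_size_px must be positive")
    if pixel_size_nm <= 0:
        raise ParameterError("pixel_size_nm must be positive")
    px_um = pixel_size_nm / 1000.0
    dt = float(disp.attrs.get("dt_s", 0.1))
    r_max = float(disp.attrs.get("r_max_um", np.inf))

    mx = (disp["x0_um"].to_numpy() + disp["x1_um"].to_numpy()) / 2.0 / px_um
    my = (disp["y0_um"].to_numpy() + disp["y1_um"].to_numpy()) / 2.0 / px_um
    bj = np.floor(mx / bin_size_px).astype(int)
    bi = np.floor(my / bin_size_px).astype(int)

    if shape_px is not None:
        n_rows = int(math.ceil(shape_px[0] / bin_size_px))
        n_cols = int(math.ceil(shape_px[1] / bin_size_px))
    elif len(disp):
        n_rows = int(bi.max()) + 1
        n_cols = int(bj.max()) + 1
    else:
        n_rows = n_cols = 1

    D = np.full((n_rows, n_cols), np.nan)
    counts = np.zeros((n_rows, n_cols), dtype=int)
    r = disp["r_um"].to_numpy()
    inside = (bi >= 0) & (bi < n_rows) & (bj >= 0) & (bj < n_cols)
    for i, j in set(zip(bi[inside].tolist(), bj[inside].tolist())):
        sel = inside & (bi == i) & (bj == j)
        counts[i, j] = int(sel.sum())
        if counts[i, j] >= n_min:
            sample = DisplacementSample(r[sel], dt_s=dt, r_max_um=r_max)
            D[i, j] = fit_single(sample, n_min=n_min).D
    return DiffusivityMap(D, counts, bin_size_px, pixel_size_nm)


def slow_fraction_per_cell(
    samples: list[DisplacementSample],
) -> pd.DataFrame:
    """Two-component fit per cell; one row per cell.

    Returns a DataFrame with columns F1, D1, D2, b, logL, n, degenerate —
    the slow fraction F1 is the statistic of interest; degenerate fits are
    flagged, not dropped. Cells with too few displacements raise
    :class:`InsufficientDataError` (propagated).
    """
    rows = []
    for sample in samples:
        fit = fit_two(sample)
        rows.append(
            (fit.F1, fit.D1, fit.D2, fit.b, fit.logL, fit.n, fit.degenerate)
        )
    return pd.DataFrame(
        rows, columns=["F1", "D1", "D2", "b", "logL", "n", "degenerate"]
    )
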