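import numpy as np
import pytest

from smrna.simulate import GroundTruthTrack, ImagingConfig, render_movie


def rayleigh_sample(a: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw |displacement| for 2D Brownian motion with scale a = 4 D dt."""
    return np.sqrt(rng.exponential(a, n))


def mixture_sample(
    n: int, f1: float, a1: float, a2: float, rng: np.random.Generator
) -> np.ndarray:
    comp = rng.random(n) < f1
    return np.where(
        comp, rayleigh_sample(a1, n, rng), rayleigh_sample(a2, n, rng)
    )


def static_tracks(positions_px, imaging: ImagingConfig):
    """Stationary ground-truth tracks at the given (x, y) pixel positions."""
    px = imaging.pixel_size_um
    tracks = []
    for k, (x, y) in enumerate(positions_px):
        tracks.append(
            GroundTruthTrack(
                k,
                np.full(imaging.n_frames, x * px),
                np.full(imaging.n_frames, y * px),
                np.array(["anchored"] * imaging.n_frames, dtype=object),
            )
        )
    return tracks


STANDARD_POSITIONS = [(12.3, 14.8), (45.2, 11.5), (30.7, 32.2), (14.1, 47.6), (49.5, 49.1)]


@pytest.fixture(scope="session")
def standard_imaging():
    """Imaging settings of the standard rendered fixture (photons 500, bg 10)."""
    return ImagingConfig(n_frames=50, height_px=64, width_px=64)


@pytest.fixture(scope="session")
def standard_movie(standard_imaging):
    """50-frame movie of 5 static emitters >= 5 px apart at SNR ~10."""
    tracks = static_tracks(STANDARD_POSITIONS, standard_imaging)
    return render_movie(tracks, standard_imaging, seed=1234)
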