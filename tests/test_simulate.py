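import numpy as np
import pytest

from smrna.core import InputError, ParameterError
from smrna.simulate import (
    GroundTruthTrack,
    ImagingConfig,
    KineticParams,
    PRESETS,
    make_geometry,
    make_two_channel_scene,
    render_movie,
    simulate_tracks,
)

from conftest import static_tracks


class TestGeometry:
    def test_nucleus_contained_in_cell(self):
        geo = make_geometry(512, 512, (200, 150), (60, 45), seed=0)
        assert geo.nucleus_mask.any()
        assert not (geo.nucleus_mask & ~geo.cell_mask).any()

    def test_oversized_nucleus_rejected(self):
        with pytest.raises(InputError):
            make_geometry(512, 512, (200, 150), (300, 300), seed=0)

    def test_same_seed_identical_masks(self):
        a = make_geometry(128, 128, (50, 40), (15, 12), seed=7, center_jitter_px=5)
        b = make_geometry(128, 128, (50, 40), (15, 12), seed=7, center_jitter_px=5)
        assert np.array_equal(a.cell_mask, b.cell_mask)
        assert np.array_equal(a.nucleus_mask, b.nucleus_mask)


class TestKinetics:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            KineticParams(F_slow=1.2)
        with pytest.raises(ParameterError):
            KineticParams(D_slow=1.0, D_fast=0.5)
        with pytest.raises(ParameterError):
            KineticParams(run_speed=-1.0)


class TestTracks:
    IMG = ImagingConfig(n_frames=20, height_px=128, width_px=128)

    def test_zero_motion_particles_are_static(self):
        geo = make_geometry(128, 128, (50, 40), (15, 12), seed=0)
        kin = KineticParams(D_fast=0.0, D_slow=0.0, F_slow=0.5, run_speed=0.0)
        tracks = simulate_tracks(geo, kin, self.IMG, 10, seed=1)
        for tr in tracks:
            assert np.ptp(tr.x_um) == 0 and np.ptp(tr.y_um) == 0

    def test_brownian_mean_square_step_matches_4_D_dt(self):
        # boundary disabled: free diffusion, E[r^2] = 4 D dt
        D, dt = 0.5, 0.1
        img = ImagingConfig(n_frames=2, height_px=4000, width_px=4000)
        kin = KineticParams(D_fast=D, D_slow=0.0, F_slow=0.0)
        tracks = simulate_tracks(None, kin, img, 10_000, seed=2)
        r2 = np.array(
            [(tr.x_um[1] - tr.x_um[0]) ** 2 + (tr.y_um[1] - tr.y_um[0]) ** 2
             for tr in tracks]
        )
        expect = 4 * D * dt
        se = r2.std(ddof=1) / np.sqrt(len(r2))
        assert abs(r2.mean() - expect) < 3 * se

    def test_directed_net_displacement_matches_speed(self):
        kin = KineticParams(
            F_slow=0.0, run_speed=1.0, pause_prob_per_step=0.0,
            reversal_prob_per_step=0.0, run_duration_mean_s=1e9,
        )
        tracks = simulate_tracks(None, kin, self.IMG, 1, seed=3)
        tr = tracks[0]
        k = self.IMG.n_frames - 1
        net = np.hypot(tr.x_um[-1] - tr.x_um[0], tr.y_um[-1] - tr.y_um[0])
        assert net == pytest.approx(k * 1.0 * 0.1, rel=1e-9)

    def test_slow_fraction_converges(self):
        geo = make_geometry(128, 128, (50, 40), (15, 12), seed=0)
        kin = KineticParams(F_slow=0.7, anchored=True)
        tracks = simulate_tracks(geo, kin, self.IMG, 2000, seed=4)
        frac = np.mean([tr.state[0] == "anchored" for tr in tracks])
        se = np.sqrt(0.7 * 0.3 / 2000)
        assert abs(frac - 0.7) < 3 * se

    def test_positions_stay_inside_cell(self):
        geo = make_geometry(128, 128, (50, 40), (15, 12), seed=0)
        kin = KineticParams(D_fast=2.0, F_slow=0.0)
        px = self.IMG.pixel_size_um
        for tr in simulate_tracks(geo, kin, self.IMG, 30, seed=5):
            ii = (tr.y_um / px).astype(int)
            jj = (tr.x_um / px).astype(int)
            assert geo.cell_mask[ii, jj].all()

    def test_same_seed_bit_identical(self):
        geo = make_geometry(128, 128, (50, 40), (15, 12), seed=0)
        kin = PRESETS["map1b_untreated"].kinetics
        a = simulate_tracks(geo, kin, self.IMG, 5, seed=6)
        b = simulate_tracks(geo, kin, self.IMG, 5, seed=6)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.x_um, tb.x_um)
            assert np.array_equal(ta.y_um, tb.y_um)
            assert np.array_equal(ta.state, tb.state)

    def test_negative_particle_count_rejected(self):
        with pytest.raises(ParameterError):
            simulate_tracks(None, KineticParams(), self.IMG, 0, seed=0)


class TestRendering:
    def test_dark_configuration_renders_zero(self):
        img = ImagingConfig(
            n_frames=3, height_px=32, width_px=32,
            photons_per_spot=0, bg_photons_per_px=0, read_noise_sd=0,
        )
        movie = render_movie(static_tracks([(16, 16)], img), img, seed=0)
        assert not movie.data.any()

    def test_noiseless_peak_at_emitter_pixel(self):
        img = ImagingConfig(
            n_frames=1, height_px=32, width_px=32,
            bg_photons_per_px=0, read_noise_sd=0,
        )
        movie = render_movie(static_tracks([(20.3, 11.7)], img), img, noise=False)
        i, j = np.unravel_index(movie.data[0].argmax(), movie.data[0].shape)
        assert (i, j) == (11, 20)

    def test_expected_photons_conserved(self):
        img = ImagingConfig(n_frames=1, height_px=64, width_px=64,
                            photons_per_spot=500, bg_photons_per_px=7)
        tracks = static_tracks([(20, 20), (40, 28), (30, 45)], img)
        movie = render_movie(tracks, img, noise=False)
        signal = movie.data[0].sum() - 7 * 64 * 64
        assert signal == pytest.approx(3 * 500, rel=1e-3)

    def test_same_seed_bit_identical(self):
        img = ImagingConfig(n_frames=2, height_px=32, width_px=32)
        tracks = static_tracks([(16, 16)], img)
        a = render_movie(tracks, img, seed=11)
        b = render_movie(tracks, img, seed=11)
        assert np.array_equal(a.data, b.data)

    def test_out_of_bounds_track_rejected(self):
        img = ImagingConfig(n_frames=1, height_px=32, width_px=32)
        with pytest.raises(ParameterError):
            render_movie(static_tracks([(40, 16)], img), img)


class TestTwoChannelScene:
    IMG = ImagingConfig(n_frames=1, height_px=128, width_px=128)

    def test_full_colocalization_no_jitter(self):
        _, _, pairs = make_two_channel_scene(50, 1.0, 0.0, self.IMG, seed=0)
        assert len(pairs) == 50
        assert np.allclose(pairs.xa_px, pairs.xb_px)
        assert np.allclose(pairs.ya_px, pairs.yb_px)

    def test_zero_colocalization_empty_pairs(self):
        _, _, pairs = make_two_channel_scene(50, 0.0, 1.0, self.IMG, seed=0)
        assert len(pairs) == 0

    def test_paired_count_binomial(self):
        _, _, pairs = make_two_channel_scene(200, 0.85, 1.0, self.IMG, seed=1)
        sd = np.sqrt(200 * 0.85 * 0.15)
        assert abs(len(pairs) - 170) <= 3 * sd

    def test_empty_scene_rejected(self):
        with pytest.raises(ParameterError):
            make_two_channel_scene(0, 0.5, 1.0, self.IMG, seed=0)
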