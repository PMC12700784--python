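import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from smrna.core import InputError, InsufficientDataError, ParameterError
from smrna.smdm import (
    DisplacementSample,
    fit_single,
    fit_two,
    loglik_single,
    loglik_two,
    map_diffusivity,
    slow_fraction_per_cell,
)

from conftest import mixture_sample, rayleigh_sample


def naive_loglik_single(D, b, r_values, dt, r_max):
    """Independent per-point oracle: direct density evaluation and summation."""
    a = 4 * D * dt
    total = 0.0
    if math.isinf(r_max):
        norm = 1.0
    else:
        norm = (1 - math.exp(-r_max**2 / a)) + b * r_max**2 / 2
    for r in r_values:
        p = (2 * r / a) * math.exp(-(r**2) / a) + b * r
        total += math.log(p / norm)
    return total


class TestLoglik:
    def test_direct_substitution(self):
        # b = 0, single r = 0.3, a = 0.2: logL = log(2*0.3/0.2) - 0.09/0.2
        sample = DisplacementSample(np.array([0.3]), dt_s=0.1, r_max_um=np.inf)
        got = loglik_single(0.5, 0.0, sample)  # a = 4*0.5*0.1 = 0.2
        assert got == pytest.approx(math.log(3.0) - 0.45, abs=1e-12)

    @pytest.mark.parametrize("D,b,r_max", [
        (0.05, 0.0, 0.5), (0.5, 1.0, 1.04), (2.0, 5.0, 1.04), (0.2, 0.3, 2.0),
    ])
    def test_density_normalized_over_truncated_support(self, D, b, r_max):
        a = 4 * D * 0.1
        norm = (1 - math.exp(-r_max**2 / a)) + b * r_max**2 / 2

        def density(r):
            return ((2 * r / a) * math.exp(-(r**2) / a) + b * r) / norm

        integral, _ = quad(density, 0.0, r_max, epsabs=1e-12)
        assert integral == pytest.approx(1.0, abs=1e-8)

    def test_mixture_density_normalized(self):
        f1, a1, a2, b, r_max = 0.7, 0.02, 0.8, 0.4, 1.04
        norm = (
            f1 * (1 - math.exp(-r_max**2 / a1))
            + (1 - f1) * (1 - math.exp(-r_max**2 / a2))
            + b * r_max**2 / 2
        )

        def density(r):
            return (
                f1 * (2 * r / a1) * math.exp(-(r**2) / a1)
                + (1 - f1) * (2 * r / a2) * math.exp(-(r**2) / a2)
                + b * r
            ) / norm

        integral, _ = quad(density, 0.0, r_max, epsabs=1e-12)
        assert integral == pytest.approx(1.0, abs=1e-8)

    def test_agrees_with_naive_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            D = rng.uniform(0.02, 3.0)
            b = rng.uniform(0.0, 2.0)
            r_max = rng.uniform(0.8, 2.0)
            r = rng.uniform(0.01, r_max, size=20)
            sample = DisplacementSample(r, dt_s=0.1, r_max_um=r_max)
            got = loglik_single(D, b, sample)
            want = naive_loglik_single(D, b, r, 0.1, r_max)
            assert got == pytest.approx(want, abs=1e-10)

    def test_sample_validation(self):
        with pytest.raises(InputError):
            DisplacementSample(np.array([0.5, 1.5]), dt_s=0.1, r_max_um=1.0)
        with pytest.raises(InputError):
            DisplacementSample(np.array([0.0]), dt_s=0.1)
        with pytest.raises(ParameterError):
            DisplacementSample(np.array([0.5]), dt_s=0.0)
        with pytest.raises(ParameterError):
            loglik_single(0.5, 1.0, DisplacementSample(np.array([0.5]), 0.1, np.inf))


class TestFitSingle:
    def test_closed_form_limit(self):
        rng = np.random.default_rng(1)
        r = rayleigh_sample(0.2, 2000, rng)
        fit = fit_single(DisplacementSample(r, 0.1, np.inf), fit_background=False)
        assert fit.a == pytest.approx(np.mean(r**2), rel=1e-6)
        assert fit.b == 0.0
        assert fit.a == pytest.approx(4 * fit.D * 0.1, rel=1e-12)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(3):
            r = rayleigh_sample(4 * 0.5 * 0.1, 500, rng)
            r = r[r <= 1.04]
            sample = DisplacementSample(r, 0.1, 1.04)
            fit = fit_single(sample)
            D_grid = np.geomspace(0.01, 5.0, 200)
            b_grid = np.linspace(0.0, 5.0, 50)
            best = max(
                loglik_single(D, b, sample) for D in D_grid for b in b_grid
            )
            assert fit.logL >= best - 0.01

    def test_recovery_from_simulation(self):
        rng = np.random.default_rng(3)
        for D in (0.05, 0.5, 2.0):
            r = rayleigh_sample(4 * D * 0.1, 10_000, rng)
            fit = fit_single(DisplacementSample(r, 0.1, np.inf),
                             fit_background=False)
            assert fit.D == pytest.approx(D, rel=0.03)

    def test_scale_equivariance_in_closed_form_limit(self):
        rng = np.random.default_rng(4)
        r = rayleigh_sample(0.1, 1000, rng)
        c = 1.7
        f1 = fit_single(DisplacementSample(r, 0.1, np.inf), fit_background=False)
        f2 = fit_single(DisplacementSample(c * r, 0.1, np.inf), fit_background=False)
        assert f2.a == pytest.approx(c**2 * f1.a, rel=1e-5)

    def test_insufficient_data_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_single(DisplacementSample(np.array([0.1] * 10), 0.1, np.inf))


class TestFitTwo:
    def test_recovery_from_simulation(self):
        rng = np.random.default_rng(5)
        r = mixture_sample(10_000, 0.7, 4 * 0.05 * 0.1, 4 * 2.0 * 0.1, rng)
        fit = fit_two(DisplacementSample(r, 0.1, np.inf))
        assert abs(fit.F1 - 0.7) <= 0.05
        assert fit.D1 == pytest.approx(0.05, rel=0.15)
        assert fit.D2 == pytest.approx(2.0, rel=0.15)
        assert not fit.degenerate

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        f1=st.floats(0.1, 0.9),
        d_ratio=st.floats(2.0, 50.0),
    )
    def test_components_always_ordered(self, seed, f1, d_ratio):
        rng = np.random.default_rng(seed)
        a1 = 0.02
        r = mixture_sample(500, f1, a1, a1 * d_ratio, rng)
        fit = fit_two(DisplacementSample(r, 0.1, np.inf))
        assert fit.D1 <= fit.D2
        assert 0.0 <= fit.F1 <= 1.0
        assert fit.a1 == pytest.approx(4 * fit.D1 * 0.1, rel=1e-9)

    def test_single_component_data_flagged(self):
        rng = np.random.default_rng(6)
        r = rayleigh_sample(4 * 0.5 * 0.1, 5000, rng)
        fit = fit_two(DisplacementSample(r, 0.1, np.inf))
        assert fit.degenerate or fit.F1 <= 0.1 or fit.F1 >= 0.9

    def test_mixture_weight_bias_across_fractions(self):
        rng = np.random.default_rng(7)
        for f1 in (0.2, 0.5, 0.8):
            r = mixture_sample(10_000, f1, 4 * 0.05 * 0.1, 4 * 2.0 * 0.1, rng)
            fit = fit_two(DisplacementSample(r, 0.1, np.inf))
            assert abs(fit.F1 - f1) <= 0.05

    def test_insufficient_data_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_two(DisplacementSample(np.full(100, 0.3), 0.1, np.inf))


class TestMap:
    def _two_region_displacements(self):
        import pandas as pd

        rng = np.random.default_rng(8)
        px = 0.13
        rows = []
        for k in range(16_000):
            left = k % 2 == 0
            D = 0.05 if left else 2.0
            x0 = rng.uniform(5, 25) * px if left else rng.uniform(35, 55) * px
            y0 = rng.uniform(5, 25) * px
            dx, dy = rng.normal(0, np.sqrt(2 * D * 0.1), 2)
            r = np.hypot(dx, dy)
            if 0 < r <= 1.04:
                rows.append((0, x0, y0, x0 + dx, y0 + dy, r))
        df = pd.DataFrame(
            rows, columns=["frame", "x0_um", "y0_um", "x1_um", "y1_um", "r_um"]
        )
        df.attrs.update(dt_s=0.1, r_max_um=1.04)
        return df

    def test_two_region_ordering(self):
        disp = self._two_region_displacements()
        dmap = map_diffusivity(disp, 130.0, 2.5, 30, shape_px=(30, 60))
        n_cols = dmap.D_um2_s.shape[1]
        left = np.nanmedian(dmap.D_um2_s[:, : n_cols // 2])
        right = np.nanmedian(dmap.D_um2_s[:, n_cols // 2 :])
        assert left < right

    def test_homogeneous_region_accuracy(self):
        import pandas as pd

        rng = np.random.default_rng(9)
        px = 0.13
        rows = []
        for _ in range(10_000):
            x0 = rng.uniform(5, 30) * px
            y0 = rng.uniform(5, 30) * px
            dx, dy = rng.normal(0, np.sqrt(2 * 0.5 * 0.1), 2)
            r = np.hypot(dx, dy)
            if 0 < r <= 1.04:
                rows.append((0, x0, y0, x0 + dx, y0 + dy, r))
        disp = pd.DataFrame(
            rows, columns=["frame", "x0_um", "y0_um", "x1_um", "y1_um", "r_um"]
        )
        disp.attrs.update(dt_s=0.1, r_max_um=1.04)
        dmap = map_diffusivity(disp, 130.0, 2.5, 30, shape_px=(35, 35))
        values = dmap.D_um2_s[np.isfinite(dmap.D_um2_s)]
        assert len(values) > 20
        frac = np.mean((values >= 0.25) & (values <= 1.0))
        assert frac >= 0.9

    def test_default_bin_edge_is_325_nm(self):
        import pandas as pd

        disp = pd.DataFrame(
            columns=["frame", "x0_um", "y0_um", "x1_um", "y1_um", "r_um"]
        )
        dmap = map_diffusivity(disp)
        assert dmap.bin_edge_nm == pytest.approx(325.0)


class TestPerCell:
    def test_empty_input_empty_output(self):
        assert len(slow_fraction_per_cell([])) == 0

    def test_pure_fast_cell_near_zero_or_degenerate(self):
        rng = np.random.default_rng(10)
        r = rayleigh_sample(4 * 2.0 * 0.1, 3000, rng)
        out = slow_fraction_per_cell([DisplacementSample(r, 0.1, np.inf)])
        row = out.iloc[0]
        assert row.degenerate or row.F1 <= 0.1
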