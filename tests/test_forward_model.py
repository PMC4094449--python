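"""Forward solver, Biot-Savart, acquisition and the flux-density noise model."""

import numpy as np
import pytest

from mreitaw import (
    ComplexImagePair,
    ConductivityImage,
    CurrentDensityMap,
    FluxDensityImage,
    Grid,
    MagnitudeImage,
    VoltageMap,
    bz_from_current,
    current_density,
    extract_bz,
    make_electrodes,
    noise_std_map,
    simulate_acquisition,
    solve_voltage,
)
from mreitaw.forward_model import GAMMA, MU0
from mreitaw.grid import shifted


class TestVoltageSolver:
    def test_uniform_strip_matches_1d_analytic_solution(self):
        """Full-edge electrodes on a uniform rectangle give a linear voltage."""
        grid = Grid(16, 16, 0.01)
        sigma = ConductivityImage(np.full(grid.shape, 2.0), grid)
        el = make_electrodes(grid, "horizontal", 0.01, width=0.16, thickness=0.004)
        u = solve_voltage(sigma, el)
        X, _ = grid.coords()
        height = grid.n_rows * grid.pixel_size
        slope = el.current / (2.0 * height * el.thickness)  # E = I/(sigma H t)
        analytic = -slope * X
        err = np.abs(u.values - analytic).max() / np.abs(analytic).max()
        assert err <= 1e-8

    def test_voltage_antisymmetric_about_midline(self):
        grid = Grid(24, 24, 0.01)
        sigma = ConductivityImage(np.ones(grid.shape), grid)
        el = make_electrodes(grid, "horizontal", 0.01, width=0.10)
        u = solve_voltage(sigma, el).values
        assert np.abs(u + u[:, ::-1]).max() <= 1e-10 * np.abs(u).max()

    def test_conductivity_scaling_halves_voltage(self, small_phantom):
        ph, els = small_phantom
        u1 = solve_voltage(ph.sigma, els[0]).values
        doubled = ConductivityImage(2.0 * ph.sigma.values, ph.sigma.grid,
                                    support=ph.support)
        u2 = solve_voltage(doubled, els[0]).values
        assert np.allclose(u2, u1 / 2.0, atol=1e-12 * np.abs(u1).max())

    def test_zero_mean_gauge(self, solved_small):
        ph, _, u, _ = solved_small
        assert abs(u.values[ph.support].mean()) <= 1e-12 * np.abs(u.values).max()


class TestCurrentDensity:
    def test_constant_gradient_case(self):
        grid = Grid(12, 12, 0.01)
        X, _ = grid.coords()
        sigma = ConductivityImage(np.full(grid.shape, 2.0), grid)
        u = VoltageMap(-X, grid, np.ones(grid.shape, dtype=bool))
        j = current_density(sigma, u)
        assert np.allclose(j.jx, 2.0)
        assert np.allclose(j.jy, 0.0)

    def test_constant_voltage_gives_zero_current(self):
        grid = Grid(12, 12, 0.01)
        sigma = ConductivityImage(np.ones(grid.shape), grid)
        u = VoltageMap(np.full(grid.shape, 3.3), grid, np.ones(grid.shape, bool))
        j = current_density(sigma, u)
        assert np.all(j.jx == 0) and np.all(j.jy == 0)

    def test_interior_flux_divergence_vanishes(self, solved_small):
        """Net face flux out of every non-electrode pixel is zero (conservation)."""
        ph, els, u, j = solved_small
        s, uv, mask = ph.sigma.values, u.values, ph.support
        p = u.grid.pixel_size
        flux_div = np.zeros(mask.shape)
        max_flux = 0.0
        for di, dj in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            nb_mask = shifted(mask, di, dj, fill=False)
            s_nb = shifted(s, di, dj)
            u_nb = shifted(uv, di, dj)
            both = mask & nb_mask
            g_face = np.where(both, 2 * s * s_nb / np.where(both, s + s_nb, 1.0), 0)
            flux = g_face * (uv - u_nb)  # per unit thickness, A/m
            flux_div += flux
            max_flux = max(max_flux, np.abs(flux).max())
        electrode_pixels = els[0].injection_map() != 0
        interior = mask & ~electrode_pixels
        assert np.abs(flux_div[interior]).max() <= 1e-6 * max_flux

    def test_grid_mismatch_rejected(self):
        g1, g2 = Grid(12, 12, 0.01), Grid(12, 12, 0.02)
        sigma = ConductivityImage(np.ones(g1.shape), g1)
        u = VoltageMap(np.zeros(g2.shape), g2, np.ones(g2.shape, bool))
        with pytest.raises(ValueError, match="grid"):
            current_density(sigma, u)


@pytest.fixture(scope="module")
def random_j():
    grid = Grid(8, 8, 0.002)
    rng = np.random.default_rng(7)
    return CurrentDensityMap(
        rng.normal(size=grid.shape), rng.normal(size=grid.shape),
        grid, np.ones(grid.shape, bool),
    )


class TestBiotSavart:
    def test_zero_current_zero_field(self):
        grid = Grid(8, 8, 0.002)
        j = CurrentDensityMap(np.zeros(grid.shape), np.zeros(grid.shape), grid,
                              np.ones(grid.shape, bool))
        for kernel in ("tall", "slab"):
            assert np.all(bz_from_current(j, 0.004, kernel=kernel).values == 0)

    @pytest.mark.parametrize("kernel", ["tall", "slab"])
    def test_single_source_pixel_hand_kernel(self, kernel):
        """One Jx pixel evaluated at an offset (0, d) along +y."""
        grid = Grid(9, 9, 0.002)
        jx = np.zeros(grid.shape)
        jx[4, 4] = 1.0
        j = CurrentDensityMap(jx, np.zeros(grid.shape), grid,
                              np.ones(grid.shape, bool))
        t = 0.004
        bz = bz_from_current(j, t, kernel=kernel).values
        p = grid.pixel_size
        for k in (1, 3):  # field point k pixels below the source (y = +k p)
            d = k * p
            if kernel == "slab":
                expected = MU0 / (4 * np.pi) * d * (p * p * t) / d**3
            else:
                expected = MU0 / (2 * np.pi) * d * (p * p) / d**2
            assert bz[4 + k, 4] == pytest.approx(expected, rel=1e-12)
        # self-pixel excluded (zero up to FFT roundoff)
        assert abs(bz[4, 4]) <= 1e-12 * np.abs(bz).max()

    @pytest.mark.parametrize("kernel", ["tall", "slab"])
    def test_fft_path_equals_brute_force(self, random_j, kernel):
        fast = bz_from_current(random_j, 0.004, kernel=kernel, method="fft").values
        slow = bz_from_current(random_j, 0.004, kernel=kernel, method="direct").values
        assert np.abs(fast - slow).max() <= 1e-12 * np.abs(slow).max()

    def test_linearity(self, random_j):
        grid = random_j.grid
        rng = np.random.default_rng(11)
        j2 = CurrentDensityMap(rng.normal(size=grid.shape),
                               rng.normal(size=grid.shape), grid,
                               random_j.support)
        a, b = 1.7, -0.4
        combo = CurrentDensityMap(a * random_j.jx + b * j2.jx,
                                  a * random_j.jy + b * j2.jy, grid,
                                  random_j.support)
        bz = bz_from_current(combo, 0.004).values
        bz_ab = (a * bz_from_current(random_j, 0.004).values
                 + b * bz_from_current(j2, 0.004).values)
        assert np.abs(bz - bz_ab).max() <= 1e-12 * np.abs(bz).max()

    def test_halving_current_halves_everything(self, small_phantom):
        ph, els = small_phantom
        el_half = make_electrodes(ph.sigma.grid, "horizontal", 0.005, ph.support,
                                  width=0.08, thickness=0.004)
        u1 = solve_voltage(ph.sigma, els[0])
        u2 = solve_voltage(ph.sigma, el_half)
        assert np.allclose(u2.values, u1.values / 2, atol=1e-12 * np.abs(u1.values).max())
        j1 = current_density(ph.sigma, u1)
        j2 = current_density(ph.sigma, u2)
        b1 = bz_from_current(j1, 0.004).values
        b2 = bz_from_current(j2, 0.004).values
        assert np.allclose(b2, b1 / 2, atol=1e-12 * np.abs(b1).max())


@pytest.fixture(scope="module")
def grid():
    return Grid(32, 32, 0.002)


class TestAcquisition:
    def test_noiseless_roundtrip_recovers_bz(self, grid):
        rng = np.random.default_rng(3)
        bz_in = rng.normal(0.0, 2e-8, grid.shape)
        m = MagnitudeImage(np.full(grid.shape, 25.0), 1e-14, grid)
        delta = rng.normal(0.0, 0.5, grid.shape)  # systematic phase cancels
        pair = simulate_acquisition(m, delta, FluxDensityImage(bz_in, grid),
                                    0.005, seed=0)
        bz_out = extract_bz(pair).values
        assert np.abs(bz_out - bz_in).max() <= 1e-12

    def test_same_seed_bit_identical(self, grid):
        m = MagnitudeImage(np.full(grid.shape, 10.0), 1.0, grid)
        bz = FluxDensityImage(np.zeros(grid.shape), grid)
        a = simulate_acquisition(m, 0.0, bz, 0.01, seed=42)
        b = simulate_acquisition(m, 0.0, bz, 0.01, seed=42)
        assert np.array_equal(a.s_plus, b.s_plus)
        assert np.array_equal(a.s_minus, b.s_minus)

    def test_phase_wrap_precondition_enforced(self, grid):
        m = MagnitudeImage(np.full(grid.shape, 10.0), 1.0, grid)
        big = FluxDensityImage(np.full(grid.shape, 1e-5), grid)
        with pytest.raises(ValueError, match="phase-wrap"):
            simulate_acquisition(m, 0.0, big, 0.01, seed=0)

    def test_extraction_hand_example(self, grid):
        """Pure phases +-theta give Bz = theta / (gamma Tc)."""
        theta, tc = 0.02675, 0.01
        pair = ComplexImagePair(
            np.full(grid.shape, np.exp(1j * theta)),
            np.full(grid.shape, np.exp(-1j * theta)),
            tc, grid,
        )
        bz = extract_bz(pair).values
        assert bz[0, 0] == pytest.approx(1.0e-8, rel=1e-12)

    def test_equal_images_give_zero_and_zero_pixels_flagged(self, grid):
        s = np.full(grid.shape, 2.0 + 1.0j)
        s[3, 3] = 0.0
        pair = ComplexImagePair(s, s.copy(), 0.01, grid)
        bz = extract_bz(pair)
        assert np.all(bz.values == 0.0)
        assert bz.invalid_mask[3, 3] and bz.invalid_mask.sum() == 1


class TestNoiseModel:
    def test_direct_evaluation(self):
        grid = Grid(8, 8, 0.002)
        m = MagnitudeImage(np.full(grid.shape, 100.0), 1.0, grid)
        sd = noise_std_map(m, 0.01).values
        assert sd[0, 0] == pytest.approx(1.0 / (2 * 26.75e7 * 0.01 * 100))
        assert sd[0, 0] == pytest.approx(1.869e-9, rel=1e-3)

    def test_doubling_tc_halves_noise(self):
        grid = Grid(8, 8, 0.002)
        m = MagnitudeImage(np.full(grid.shape, 50.0), 1.0, grid)
        assert np.allclose(noise_std_map(m, 0.02).values,
                           noise_std_map(m, 0.01).values / 2.0)

    def test_low_snr_clamped_and_flagged(self):
        grid = Grid(8, 8, 0.002)
        vals = np.full(grid.shape, 10.0)
        vals[0, 0] = 1.0  # SNR 1 < 2.8
        m = MagnitudeImage(vals, 1.0, grid)
        nm = noise_std_map(m, 0.01)
        assert nm.low_snr_mask[0, 0] and nm.low_snr_mask.sum() == 1
        assert nm.values[0, 0] == pytest.approx(1.0 / (2 * GAMMA * 0.01 * 2.8))

    @pytest.mark.parametrize("snr", [10, 50, 100])
    def test_monte_carlo_matches_model(self, snr):
        """Sample std of extracted Bz over 10^4 pixels tracks the model."""
        grid = Grid(100, 100, 0.001)
        tc = 0.01
        m = MagnitudeImage(np.full(grid.shape, float(snr)), 1.0, grid)
        pair = simulate_acquisition(m, 0.0, FluxDensityImage(np.zeros(grid.shape), grid),
                                    tc, seed=snr)
        sd_mc = extract_bz(pair).values.std()
        assert sd_mc == pytest.approx(1.0 / (2 * GAMMA * tc * snr), rel=0.05)
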