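"""Units, window planning, WHAM, autocorrelation, diffusion, residence time."""

import numpy as np
import pytest

from helixevo import synthdata, thermo
from helixevo.thermo import (
    DiffusionProfile,
    FreeEnergyProfile,
    ThermalContext,
    UmbrellaWindow,
    arrhenius_ratio,
    autocorr_time,
    diffusion_from_window,
    from_kbt,
    plan_windows,
    residence_time,
    to_kbt,
    wham,
)

CTX300 = ThermalContext(300.0)
CTX303 = ThermalContext(303.15)


class TestUnits:
    def test_5_kj_mol_is_2_kbt(self):
        assert to_kbt(5.0, CTX300) == pytest.approx(2.005, abs=0.005)
        assert round(float(to_kbt(5.0, CTX300))) == 2

    def test_zero(self):
        assert to_kbt(0.0, CTX300) == 0.0

    def test_inverse_property(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_allclose(to_kbt(from_kbt(x, CTX303), CTX303), x,
                                   rtol=1e-12)

    def test_beta_kbt_identity(self):
        assert CTX303.beta * CTX303.kbt == pytest.approx(1.0)

    def test_arrhenius_14_kbt(self):
        assert arrhenius_ratio(14.0) == pytest.approx(1.2e6, rel=0.01)
        assert arrhenius_ratio(0.0) == 1.0

    def test_arrhenius_multiplicative(self, rng):
        a, b = rng.normal(size=2)
        assert arrhenius_ratio(a + b) == pytest.approx(
            arrhenius_ratio(a) * arrhenius_ratio(b))


class TestPlanWindows:
    def test_production_protocol_nine_windows(self):
        centers = plan_windows(0.7, 2.3, 0.2)
        assert len(centers) == 9
        np.testing.assert_allclose(centers, 0.7 + 0.2 * np.arange(9))

    def test_two_point_grid(self):
        np.testing.assert_allclose(plan_windows(0, 1, 1), [0.0, 1.0])

    def test_count_formula_random_triples(self, rng):
        for _ in range(50):
            lo = float(rng.uniform(-2, 2))
            n = int(rng.integers(1, 30))
            s = float(rng.uniform(0.05, 0.5))
            centers = plan_windows(lo, lo + n * s, s)
            assert len(centers) == n + 1

    def test_non_divisible_range_suggests_spacing(self):
        with pytest.raises(ValueError, match="nearest valid"):
            plan_windows(0.0, 1.0, 0.3)


class TestWham:
    def test_unbiased_uniform_is_flat(self, rng):
        samples = rng.uniform(0.0, 1.0, size=40_000)
        window = UmbrellaWindow(center=0.5, spring_k=0.0, samples=samples)
        grid = np.linspace(0.05, 0.95, 19)
        profile = wham([window], grid, CTX303)
        assert profile.G.max() < 0.15 * CTX303.kbt

    def test_single_harmonic_window_boltzmann_closed_form(self, rng):
        # biased sampling on a flat landscape: Gaussian with Var = kBT/k
        k = 250.0
        sigma = np.sqrt(CTX303.kbt / k)
        samples = rng.normal(1.0, sigma, size=80_000)
        window = UmbrellaWindow(center=1.0, spring_k=k, samples=samples)
        grid = np.linspace(1.0 - 3 * sigma, 1.0 + 3 * sigma, 41)
        profile = wham([window], grid, CTX303)
        # unbiased estimate must be flat despite the strongly peaked histogram
        # (assessed over the well-sampled +-2 sigma region)
        core = np.abs(profile.x - 1.0) <= 2 * sigma
        g_core = profile.G[core] - profile.G[core].min()
        assert np.sqrt(np.mean(g_core ** 2)) < 0.2 * CTX303.kbt
        assert np.var(samples) == pytest.approx(CTX303.kbt / k, rel=0.05)

    def test_recovers_double_well_from_langevin(self):
        pmf = synthdata.double_well_pmf(CTX303)
        centers = plan_windows(0.7, 2.3, 0.2)
        series = synthdata.umbrella_series(pmf, centers, 250.0, 60_000,
                                           dt=0.01, D=0.05, context=CTX303,
                                           seed=3, burn_in=2000)
        windows = [UmbrellaWindow(c, 250.0, s)
                   for c, s in zip(centers, series)]
        grid = np.arange(0.6, 2.4 + 1e-9, 0.02)
        profile = wham(windows, grid, CTX303)
        mask = (profile.x >= 0.7) & (profile.x <= 2.3)
        truth = pmf(profile.x[mask])
        truth -= truth.min()
        est = profile.G[mask] - profile.G[mask].min()
        rmse_kbt = np.sqrt(np.mean((est - truth) ** 2)) / CTX303.kbt
        assert rmse_kbt < 0.2

    def test_gauge_invariance_min_normalized(self, rng):
        samples = rng.normal(1.0, 0.1, size=5000)
        window = UmbrellaWindow(center=1.0, spring_k=250.0, samples=samples)
        grid = np.linspace(0.7, 1.3, 31)
        profile = wham([window], grid, CTX303)
        assert profile.G.min() == 0.0

    def test_gap_in_sampling_rejected(self, rng):
        w1 = UmbrellaWindow(0.5, 500.0, rng.normal(0.5, 0.05, 2000))
        w2 = UmbrellaWindow(2.5, 500.0, rng.normal(2.5, 0.05, 2000))
        with pytest.raises(ValueError, match="gap"):
            wham([w1, w2], np.linspace(0.3, 2.7, 121), CTX303)

    def test_empty_window_rejected(self, rng):
        w = UmbrellaWindow(5.0, 250.0, rng.normal(5.0, 0.05, 100))
        with pytest.raises(ValueError, match="no samples"):
            wham([w], np.linspace(0.0, 1.0, 11), CTX303)


class TestAutocorr:
    def test_white_noise_theta_is_dt(self, rng):
        theta = autocorr_time(rng.normal(size=50_000), dt=2.0)
        assert theta == pytest.approx(2.0, rel=0.15)

    def test_ar1_closed_form(self, rng):
        phi = 0.9
        n = 200_000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        # one-sided ACF integral: sum phi^k = 1/(1-phi)
        assert autocorr_time(x, dt=1.0) == pytest.approx(1 / (1 - phi), rel=0.15)

    def test_strong_correlation_grows_theta(self, rng):
        white = rng.normal(size=2000)
        duplicated = np.repeat(rng.normal(size=100), 20)
        assert autocorr_time(duplicated, 1.0) > 10 * autocorr_time(white, 1.0)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            autocorr_time(np.ones(500), 1.0)

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="100"):
            autocorr_time(np.arange(50.0), 1.0)


class TestDiffusion:
    D_TRUE = 0.05
    DT = 0.01

    def _window(self, k, seed=7):
        spec = synthdata.LangevinSpec(
            pmf=synthdata.flat_pmf(), D=self.D_TRUE, dt=self.DT,
            n_steps=100_000, x_init=1.0, context=CTX303, seed=seed,
            bias_center=1.0, bias_k=k)
        return UmbrellaWindow(1.0, k, synthdata.langevin_1d(spec))

    def test_recovers_simulator_D_within_20_percent(self):
        D_hat = diffusion_from_window(self._window(250.0), self.DT)
        assert D_hat == pytest.approx(self.D_TRUE, rel=0.20)

    @pytest.mark.parametrize("k", [50.0, 250.0, 1000.0])
    def test_invariant_to_spring_constant(self, k):
        # Var halves when k doubles, and so does theta; D = Var/theta is flat
        D_hat = diffusion_from_window(self._window(k), self.DT)
        assert D_hat == pytest.approx(self.D_TRUE, rel=0.20)

    def test_variance_scales_inversely_with_k(self):
        v250 = np.var(self._window(250.0).samples)
        v500 = np.var(self._window(500.0, seed=8).samples)
        assert v250 / v500 == pytest.approx(2.0, rel=0.1)

    def test_constant_series_errors(self):
        w = UmbrellaWindow(1.0, 250.0, np.full(500, 1.0))
        with pytest.raises(ValueError):
            diffusion_from_window(w, 0.01)


class TestResidenceTime:
    def test_flat_landscape_closed_form(self):
        grid = np.linspace(0.5, 2.0, 151)
        G = FreeEnergyProfile(grid, np.zeros_like(grid), CTX303)
        D = DiffusionProfile.constant(1.0)
        tau = residence_time(G, D, 0.70, 1.80, 0.62)
        expected = ((1.80 - 0.62) ** 2 - (0.70 - 0.62) ** 2) / 2.0
        assert tau == pytest.approx(expected, rel=1e-4)
        assert tau == pytest.approx(0.6930, abs=1e-3)

    def test_matches_direct_simulation_on_2kbt_well(self):
        pmf = synthdata.single_well_pmf(2.0, center=0.9, width=0.15,
                                        context=CTX303)
        D = 0.05
        grid = np.linspace(0.55, 2.0, 146)
        G = FreeEnergyProfile(grid, pmf(grid), CTX303)
        tau_integral = residence_time(G, DiffusionProfile.constant(D),
                                      0.70, 1.80, 0.62)
        spec = synthdata.LangevinSpec(pmf=pmf, D=D, dt=0.01, n_steps=1,
                                      x_init=0.70, context=CTX303, seed=11,
                                      probe_range=(0.5, 2.2))
        tau_direct = synthdata.mfpt_direct(spec, 0.70, 1.80, 0.62, n_traj=2000)
        assert tau_direct == pytest.approx(tau_integral, rel=0.15)

    def test_deepening_the_well_increases_tau(self):
        grid = np.linspace(0.55, 2.0, 146)
        D = DiffusionProfile.constant(0.05)
        taus = []
        for depth in (1.0, 2.0, 3.0):
            pmf = synthdata.single_well_pmf(depth, context=CTX303)
            G = FreeEnergyProfile(grid, pmf(grid), CTX303)
            taus.append(residence_time(G, D, 0.70, 1.80, 0.62))
        assert taus[0] < taus[1] < taus[2]

    def test_tau_scales_inversely_with_D(self):
        grid = np.linspace(0.55, 2.0, 146)
        pmf = synthdata.single_well_pmf(2.0, context=CTX303)
        G = FreeEnergyProfile(grid, pmf(grid), CTX303)
        tau1 = residence_time(G, DiffusionProfile.constant(0.05),
                              0.70, 1.80, 0.62)
        tau2 = residence_time(G, DiffusionProfile.constant(0.10),
                              0.70, 1.80, 0.62)
        assert tau1 / tau2 == pytest.approx(2.0, rel=1e-6)

    def test_invalid_limits_rejected(self):
        grid = np.linspace(0.5, 2.0, 16)
        G = FreeEnergyProfile(grid, np.zeros_like(grid), CTX303)
        D = DiffusionProfile.constant(1.0)
        with pytest.raises(ValueError):
            residence_time(G, D, 1.8, 0.7, 0.62)
        with pytest.raises(ValueError):
            residence_time(G, D, 0.7, 1.8, 0.75)

    def test_profile_tsv_round_trip(self, tmp_path):
        grid = np.linspace(0.7, 2.3, 33)
        pmf = synthdata.double_well_pmf(CTX303)
        profile = FreeEnergyProfile(grid, pmf(grid), CTX303)
        profile.to_tsv(tmp_path / "pmf.tsv")
        back = FreeEnergyProfile.from_tsv(tmp_path / "pmf.tsv", CTX303)
        np.testing.assert_allclose(back.x, profile.x, atol=1e-9)
        np.testing.assert_allclose(back.G, profile.G, atol=1e-9)
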