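"""Window layout, WHAM reconstruction and the profile fits, checked against
analytic generators."""
import warnings

import numpy as np
import pytest

from porecv.free_energy import (KB, FreeEnergyProfile, UmbrellaWindow,
                                block_convergence, bootstrap_error,
                                fit_line_tension_profile, fit_quadratic,
                                halves_error, make_window_centers,
                                seed_windows, wham_solve)

KT = KB * 310.0


def _profile(grid, G):
    grid = np.asarray(grid, dtype=float)
    G = np.asarray(G, dtype=float)
    return FreeEnergyProfile(grid=grid, G=G, err=np.zeros_like(G),
                             reference=int(np.argmin(G)),
                             sampled=np.ones_like(G, dtype=bool))


class TestWindowCenters:
    def test_fullpath_production_grid(self):
        centers = make_window_centers(-0.100, 2.175, spacing=0.035)
        assert len(centers) == 66
        assert centers[0] == pytest.approx(-0.100)
        assert centers[-1] == pytest.approx(2.175)

    def test_rapid_grid_spacing(self):
        centers = make_window_centers(6.0, 6.6, count=21)
        assert len(centers) == 21
        assert np.diff(centers)[0] == pytest.approx(0.03)

    def test_oversized_spacing_rejected(self):
        with pytest.raises(ValueError):
            make_window_centers(0.0, 1.0, spacing=2.0)

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError):
            make_window_centers(0.0, 1.0, spacing=0.0)


class TestSeedWindows:
    def test_exact_match_selected(self):
        cv = [0.0, 0.5, 1.0, 1.5]
        assert seed_windows(cv, [0.5])[0] == 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            seed_windows([0.0, 1.0], [2.0])

    def test_tie_breaks_to_earlier_frame(self):
        cv = [0.4, 0.6, 0.6, 0.4]
        assert seed_windows(cv, [0.5])[0] == 0


class TestWham:
    def test_flat_profile_from_uniform_density(self):
        rng = np.random.default_rng(0)
        # near-unbiased window: kappa so soft the bias is < 0.01 kT anywhere
        w = UmbrellaWindow(center=0.5, kappa=1e-6,
                           samples=rng.uniform(0, 1, 200_000))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = wham_solve([w], n_bins=20)
        G = prof.G - np.nanmean(prof.G)  # flat up to the arbitrary offset
        assert np.nanmax(np.abs(G)) < 0.1  # sampling-noise bound

    def test_linear_potential_slope_recovered(self):
        # exact inverse-CDF samples from two overlapping biased windows on
        # G(x) = m x
        m_true = 8.0
        rng = np.random.default_rng(2)
        kappa = 200.0
        windows = []
        for c in (0.0, 0.25, 0.5):
            x = np.linspace(c - 1.5, c + 1.5, 40001)
            logp = -(m_true * x + 0.5 * kappa * (x - c) ** 2) / KT
            p = np.exp(logp - logp.max())
            cdf = np.cumsum(p)
            cdf /= cdf[-1]
            samples = np.interp(rng.uniform(size=40_000), cdf, x)
            windows.append(UmbrellaWindow(center=c, kappa=kappa, samples=samples))
        prof = wham_solve(windows, n_bins=60)
        mask = prof.sampled
        slope = np.polyfit(prof.grid[mask], prof.G[mask], 1)[0]
        assert slope == pytest.approx(m_true, rel=0.02)

    def test_profile_minimum_is_zero_at_reference(self):
        from porecv.pipelines import sample_doublewell_windows

        prof = wham_solve(sample_doublewell_windows(seed=3, n_windows=8,
                                                    n_samples=500, kappa=500.0),
                          n_bins=50)
        assert np.nanmin(prof.G) == 0.0
        assert prof.G[prof.reference] == 0.0

    def test_window_order_invariance(self):
        from porecv.pipelines import sample_doublewell_windows

        windows = sample_doublewell_windows(seed=4, n_windows=6,
                                            n_samples=1000, kappa=200.0)
        bins = np.linspace(-0.8, 0.8, 81)
        a = wham_solve(windows, bins=bins)
        b = wham_solve(windows[::-1], bins=bins)
        m = a.sampled & b.sampled
        assert np.allclose(a.G[m], b.G[m], atol=1e-6)

    def test_mixed_temperatures_rejected(self):
        w1 = UmbrellaWindow(0.0, 10.0, [0.0, 0.1], temperature=300.0)
        w2 = UmbrellaWindow(0.1, 10.0, [0.1, 0.2], temperature=310.0)
        with pytest.raises(ValueError, match="temperature"):
            wham_solve([w1, w2])

    def test_poor_overlap_warns(self):
        rng = np.random.default_rng(5)
        w1 = UmbrellaWindow(0.0, 5000.0, rng.normal(0.0, 0.02, 1000))
        w2 = UmbrellaWindow(1.0, 5000.0, rng.normal(1.0, 0.02, 1000))
        with pytest.warns(UserWarning, match="overlap|share"):
            wham_solve([w1, w2], n_bins=100, max_iter=200000)


class TestQuadraticFit:
    def test_exact_quadratic(self):
        grid = np.linspace(0, 0.5, 20)
        fit = fit_quadratic(_profile(grid, 3.0 * grid ** 2))
        assert fit.k == pytest.approx(3.0, abs=1e-12)
        assert fit.c == pytest.approx(0.0, abs=1e-12)

    def test_intercept_recovered(self):
        grid = np.linspace(0, 0.5, 20)
        fit = fit_quadratic(_profile(grid, 3.0 * grid ** 2 + 1.0))
        assert fit.k == pytest.approx(3.0, abs=1e-12)
        assert fit.c == pytest.approx(1.0, abs=1e-12)

    def test_range_filter_excludes_outlier(self):
        grid = np.linspace(0, 0.6, 25)
        G = 3.0 * grid ** 2
        G[grid > 0.5] += 50.0  # out-of-range bins must not matter
        fit = fit_quadratic(_profile(grid, G))
        assert fit.k == pytest.approx(3.0, abs=1e-12)

    def test_insufficient_bins_rejected(self):
        with pytest.raises(ValueError):
            fit_quadratic(_profile([0.1, 0.2], [0.0, 0.1]))


class TestLineTensionFit:
    def test_fullpath_inverse_of_construction(self):
        gamma0 = 2.0
        grid = np.linspace(1.2, 2.2, 30)
        prof = _profile(grid, 2 * np.pi * gamma0 * grid)
        res = fit_line_tension_profile(prof, mode="fullpath")
        assert res.gamma_kjmolnm == pytest.approx(gamma0, rel=1e-12)

    def test_rapid_conversion(self):
        grid = np.linspace(6.0, 6.6, 21)
        prof = _profile(grid, 10.0 * grid)
        res = fit_line_tension_profile(prof, mode="rapid")
        assert res.gamma_pN == pytest.approx(10 * 1.66054 / 2, rel=1e-5)

    def test_flat_profile_zero_tension(self):
        grid = np.linspace(1.2, 2.0, 10)
        res = fit_line_tension_profile(_profile(grid, np.zeros(10)),
                                       mode="fullpath")
        assert res.gamma_pN == pytest.approx(0.0, abs=1e-12)


class TestErrors:
    def test_halves_identical_gives_zero(self):
        w = UmbrellaWindow(0.0, 10.0, np.tile([0.1, 0.2], 10))
        # estimator = mean of first window's samples
        err = halves_error([w], lambda ws: float(ws[0].samples.mean()))
        assert err == 0.0

    def test_halves_of_known_values(self):
        w = UmbrellaWindow(0.0, 10.0, np.concatenate([np.full(5, 10.0),
                                                      np.full(5, 12.0)]))
        err = halves_error([w], lambda ws: float(ws[0].samples.mean()))
        assert err == 1.0

    def test_halves_error_shrinks_with_samples(self):
        from porecv.pipelines import sample_doublewell_windows

        def estimator(ws):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                prof = wham_solve(ws, n_bins=40, tol=1e-6)
            return fit_quadratic(prof, cv_max=0.5).k

        errs = []
        for n in (1000, 10000):
            windows = sample_doublewell_windows(seed=6, n_windows=10,
                                                n_samples=n, lo=-0.4, hi=0.4)
            errs.append(halves_error(windows, estimator))
        assert errs[1] < errs[0]

    def test_bootstrap_degenerate_samples_zero_error(self):
        w1 = UmbrellaWindow(0.0, 50.0, np.full(100, 0.0))
        w2 = UmbrellaWindow(0.1, 50.0, np.full(100, 0.1))
        err = bootstrap_error([w1, w2], n_boot=5, n_bins=10)
        assert np.nanmax(err) == 0.0

    def test_bootstrap_single_replicate_zero(self):
        rng = np.random.default_rng(7)
        w1 = UmbrellaWindow(0.0, 50.0, rng.normal(0, 0.2, 200))
        w2 = UmbrellaWindow(0.2, 50.0, rng.normal(0.2, 0.2, 200))
        err = bootstrap_error([w1, w2], n_boot=1, n_bins=20)
        assert np.nanmax(err) == 0.0

    def test_bootstrap_calibration_against_analytic(self):
        from porecv.pipelines import (doublewell_free_energy,
                                      sample_doublewell_windows)

        windows = sample_doublewell_windows(seed=8, n_windows=10,
                                            n_samples=2000, lo=-0.45, hi=0.45)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = wham_solve(windows, n_bins=60)
            err = bootstrap_error(windows, n_boot=60, seed=1, n_bins=60)
        G_true = doublewell_free_energy(10.0)(prof.grid)
        mask = prof.sampled & (err > 0)
        diff = prof.G[mask] - G_true[mask]
        diff -= diff.mean()
        frac = np.mean(np.abs(diff) < 1.5 * err[mask])
        assert frac >= 0.60  # ~68% coverage band

    def test_single_window_bootstrap_rejected(self):
        w = UmbrellaWindow(0.0, 50.0, np.zeros(10))
        with pytest.raises(ValueError):
            bootstrap_error([w])


class TestBlockConvergence:
    def test_single_block_matches_full_solve(self):
        from porecv.pipelines import sample_doublewell_windows

        windows = sample_doublewell_windows(seed=9, n_windows=6,
                                            n_samples=1000, lo=-0.3, hi=0.3)
        bins = np.linspace(-0.4, 0.4, 41)
        profiles, dev = block_convergence(windows, 1, bins=bins)
        full = wham_solve(windows, bins=bins)
        m = full.sampled
        assert np.allclose(profiles[0].G[m], full.G[m], atol=1e-6)
        assert dev == 0.0

    def test_stationary_blocks_agree(self):
        from porecv.pipelines import sample_doublewell_windows

        windows = sample_doublewell_windows(seed=10, n_windows=8,
                                            n_samples=2000, lo=-0.4, hi=0.4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, dev = block_convergence(windows, 2, n_bins=40)
            err = bootstrap_error(windows, n_boot=40, seed=2, n_bins=40)
        assert dev < 3 * max(np.nanmax(err), 0.5)

    def test_unequal_blocks_rejected(self):
        w = UmbrellaWindow(0.0, 50.0, np.zeros(10))
        with pytest.raises(ValueError):
            block_convergence([w], 3)
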