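"""Toy Langevin engine: force/energy consistency, integrator limits,
determinism and biased-sampling statistics."""
from dataclasses import replace

import numpy as np
import pytest

from porecv.cv_fullpath import CVParams, calibrate_cv_eq
from porecv.cv_rapid import BiasSpec
from porecv.membranes import (HEAD, TAIL, TERMINAL_TAIL, GeometrySpec,
                              ParticleConfiguration, build_flat_bilayer)
from porecv.toy_md import (HarmonicTether, SimulationSettings,
                           StripeFlatBottomBias, ToyForceField, energy_forces,
                           initialize_state, langevin_step, minimize,
                           run_langevin, run_window, steered_pull)

FF = ToyForceField()
NO_TOPOLOGY = (np.empty((0, 2), dtype=np.int64), np.empty((0, 2), dtype=np.int64))


def _free_beads(positions, roles=None, lipid_ids=None, box=12.0):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return ParticleConfiguration(
        positions, roles if roles is not None else np.full(n, TAIL),
        lipid_ids if lipid_ids is not None else np.full(n, -1), [box] * 3)


def _fd_forces(cfg, ff, topology, h=1e-6):
    num = np.zeros_like(cfg.positions)
    for i in range(cfg.n_particles):
        for ax in range(3):
            cp = cfg.copy()
            cp.positions[i, ax] += h
            cm = cfg.copy()
            cm.positions[i, ax] -= h
            ep, _ = energy_forces(cp, ff, topology=topology)
            em, _ = energy_forces(cm, ff, topology=topology)
            num[i, ax] = -(ep - em) / (2 * h)
    return num


class TestPotentialTerms:
    def test_wca_pair_forces_match_finite_differences(self):
        cfg = _free_beads([[5.0, 5.0, 5.0], [5.4, 5.2, 5.1]])
        _, f = energy_forces(cfg, FF, topology=NO_TOPOLOGY)
        num = _fd_forces(cfg, FF, NO_TOPOLOGY)
        assert np.abs(f - num).max() < 1e-4

    def test_attraction_pair_forces_match_finite_differences(self):
        # beads on different lipids inside the attraction shell
        cfg = _free_beads([[5.0, 5.0, 5.0], [6.1, 5.3, 5.2]],
                          lipid_ids=[0, 1])
        e, f = energy_forces(cfg, FF, topology=NO_TOPOLOGY)
        assert e < 0  # attractive region
        num = _fd_forces(cfg, FF, NO_TOPOLOGY)
        assert np.abs(f - num).max() < 1e-4

    def test_attraction_minimum_has_zero_force(self):
        rc = 2 ** (1 / 6) * FF.bead_diameter
        cfg = _free_beads([[5.0, 5.0, 5.0], [5.0 + rc, 5.0, 5.0]],
                          lipid_ids=[0, 1])
        _, f = energy_forces(cfg, FF, topology=NO_TOPOLOGY)
        assert np.abs(f).max() < 1e-8

    def test_bonded_lipid_forces_match_finite_differences(self):
        cfg = _free_beads([[5.0, 5.0, 4.6], [5.05, 5.0, 5.25], [5.0, 5.1, 5.9]],
                          roles=[TERMINAL_TAIL, TAIL, HEAD], lipid_ids=[0, 0, 0])
        _, f = energy_forces(cfg, FF)
        num = _fd_forces(cfg, FF, None)
        assert np.abs(f - num).max() < 1e-4

    def test_random_bilayer_forces_match_finite_differences(self):
        cfg = build_flat_bilayer(GeometrySpec(n_lipids=10, seed=6,
                                              water_density=0.0,
                                              area_per_lipid=0.5,
                                              leaflet_separation=0.7))
        cfg = minimize(cfg, FF, n_steps=50)
        rng = np.random.default_rng(3)
        cfg.positions += rng.normal(0, 0.01, cfg.positions.shape)
        _, f = energy_forces(cfg, FF)
        num = _fd_forces(cfg, FF, None)
        assert np.abs(f - num).max() < 1e-4

    def test_isolated_particle_zero_force(self):
        cfg = _free_beads([[5.0, 5.0, 5.0]])
        e, f = energy_forces(cfg, FF, topology=NO_TOPOLOGY)
        assert e == 0.0 and np.all(f == 0.0)

    def test_overlap_detected(self):
        cfg = _free_beads([[5.0, 5.0, 5.0], [5.05, 5.0, 5.0]])
        with pytest.raises(ValueError, match="overlap"):
            energy_forces(cfg, FF, topology=NO_TOPOLOGY)


class TestIntegrator:
    def test_ballistic_limit(self):
        # zero friction, no forces: straight-line motion at initial velocity
        cfg = _free_beads([[50.0, 50.0, 50.0]], box=100.0)
        settings = SimulationSettings(seed=4, timestep=0.01, friction=0.0)
        state = initialize_state(cfg, FF, settings)
        v0 = state.velocities[0].copy()
        for _ in range(100):
            langevin_step(state, FF, settings)
        drift = state.config.positions[0] - 50.0
        assert np.allclose(drift, v0 * 1.0, atol=1e-10)

    def test_fixed_seed_reproducible(self):
        cfg = _free_beads([[5.0, 5.0, 5.0], [6.5, 5.0, 5.0]])
        def run():
            settings = SimulationSettings(seed=12, timestep=0.01)
            state = initialize_state(cfg, FF, settings)
            for _ in range(200):
                langevin_step(state, FF, settings)
            return state.config.positions.copy()
        assert np.array_equal(run(), run())

    def test_harmonic_well_equipartition(self):
        # position variance of a tethered bead must match kT/k within 5%
        cfg = _free_beads([[5.0, 5.0, 5.0]])
        settings = SimulationSettings(seed=3, timestep=0.02, friction=1.0)
        k = 10.0
        tether = HarmonicTether([0], k, np.array([5.0, 5.0, 5.0]))
        out = run_langevin(cfg, FF, settings, biases=[tether],
                           n_steps=100_000, sample_every=10,
                           recorders={"x": lambda s: s.config.positions[0, 0]})
        var = out["series"]["x"].to_numpy().var()
        assert var == pytest.approx(settings.kT / k, rel=0.05)

    def test_blowup_detected(self):
        # an absurd timestep stretches a FENE bond past its divergence length
        cfg = _free_beads([[5.0, 5.0, 4.6], [5.0, 5.0, 5.25], [5.0, 5.0, 5.9]],
                          roles=[TERMINAL_TAIL, TAIL, HEAD], lipid_ids=[0, 0, 0])
        settings = SimulationSettings(seed=5, timestep=50.0, friction=0.0)
        state = initialize_state(cfg, FF, settings)
        state.velocities[0] = [0.0, 0.0, -1.0]
        state.velocities[2] = [0.0, 0.0, 1.0]
        with pytest.raises(ValueError):
            for _ in range(100):
                langevin_step(state, FF, settings)


class TestBiasForces:
    def test_flat_bottom_bias_force_is_exact_gradient(self):
        cfg = build_flat_bilayer(GeometrySpec(n_lipids=8, seed=7,
                                              water_density=0.0))
        # pull one head far out so the restraint engages (the reference is
        # the instantaneous head mean, which the displacement also shifts)
        heads = np.where(cfg.roles == HEAD)[0]
        cfg.positions[heads[0], 0] += 4.5
        bias = StripeFlatBottomBias(BiasSpec(kind="flat_bottom", k_fb=1000.0,
                                             half_width=2.5), axis=0)
        e0, f = bias.energy_forces(cfg, 0.0)
        assert e0 > 0
        h = 1e-6
        for i in heads[:4]:
            cp = cfg.copy()
            cp.positions[i, 0] += h
            cm = cfg.copy()
            cm.positions[i, 0] -= h
            num = -(bias.energy_forces(cp, 0.0)[0]
                    - bias.energy_forces(cm, 0.0)[0]) / (2 * h)
            assert f[i, 0] == pytest.approx(num, abs=1e-4)


@pytest.fixture(scope="module")
def small_toy_bilayer():
    from porecv.pipelines import toy_bilayer_config

    return toy_bilayer_config(60, seed=0)


@pytest.fixture(scope="module")
def toy_cv_params(small_toy_bilayer):
    params = CVParams(r_cyl=0.8)
    return replace(params, cv_eq=calibrate_cv_eq([small_toy_bilayer],
                                                 params).cv_eq)


class TestBiasedSampling:
    def test_zero_length_schedule_matches_unbiased(self, small_toy_bilayer,
                                                   toy_cv_params):
        settings = SimulationSettings(seed=8, timestep=0.02)
        cv0 = 0.0  # schedule pinned at a centre with zero force constant
        frames, series = steered_pull(small_toy_bilayer, FF, settings,
                                      toy_cv_params, cv0, cv0, kappa=0.0,
                                      n_steps=300, sample_every=100)
        out = run_langevin(small_toy_bilayer, FF, settings, n_steps=300,
                           sample_every=100)
        assert np.allclose(frames[-1].positions,
                           out["state"].config.positions)

    def test_pull_moves_cv_monotonically(self, small_toy_bilayer,
                                         toy_cv_params):
        from scipy.stats import spearmanr

        settings = SimulationSettings(seed=9, timestep=0.02)
        _, series = steered_pull(small_toy_bilayer, FF, settings,
                                 toy_cv_params, 0.05, 0.6, kappa=1500.0,
                                 n_steps=6000, sample_every=20)
        rho = spearmanr(series["time"], series["cv"]).statistic
        assert rho > 0.8

    def test_stiff_window_gaussian_statistics(self, small_toy_bilayer,
                                              toy_cv_params):
        settings = SimulationSettings(seed=10, timestep=0.02)
        kappa = 20000.0
        center = 0.10
        samples, series = run_window(small_toy_bilayer, FF, settings,
                                     toy_cv_params, center=center,
                                     kappa=kappa, n_steps=8000,
                                     sample_every=10, keep_fraction=0.5)
        # stiff-spring limit: mean ~ centre, std ~ sqrt(kT/kappa)
        assert samples.mean() == pytest.approx(center, abs=0.05)
        assert samples.std() == pytest.approx(np.sqrt(settings.kT / kappa),
                                              rel=0.5)

    def test_keep_fraction_one_keeps_everything(self, small_toy_bilayer,
                                                toy_cv_params):
        settings = SimulationSettings(seed=11, timestep=0.02)
        samples, series = run_window(small_toy_bilayer, FF, settings,
                                     toy_cv_params, center=0.1, kappa=500.0,
                                     n_steps=400, sample_every=100,
                                     keep_fraction=1.0)
        assert len(samples) == len(series)
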