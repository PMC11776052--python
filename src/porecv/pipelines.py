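"""End-to-end protocols at desk scale.

These functions wire the package together on synthetic systems: the
double-well WHAM oracle (exact inverse-CDF sampling of biased Boltzmann
densities), the toy Full-Path umbrella pipeline with a forward/reverse
hysteresis check, and the toy-stripe Rapid pipeline yielding a line tension.
All problem sizes here are deliberately small (tens of lipids, short runs);
they are the package's standard demonstration scale, chosen so a full
pipeline completes in minutes on one core.  Every function takes a seed and
is deterministic given it.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .cv_fullpath import CVParams, calibrate_cv_eq
from .cv_rapid import BiasSpec, LineTensionResult
from .free_energy import (KB, FreeEnergyProfile, QuadraticFit, UmbrellaWindow,
                          fit_line_tension_profile, fit_quadratic,
                          halves_error, make_window_centers, wham_solve)
from .membranes import (GeometrySpec, ParticleConfiguration,
                        build_flat_bilayer, build_stripe)
from .pore_state import PoreStateSeries, fit_pore_lifetime, tanh_decay
from .toy_md import (RimLengthBias, SimulationSettings, StripeFlatBottomBias,
                     ToyForceField, minimize, run_langevin, run_window,
                     steered_pull)

__all__ = [
    "doublewell_free_energy",
    "sample_doublewell_windows",
    "wham_doublewell_rms",
    "toy_bilayer_config",
    "toy_stripe_config",
    "toy_fullpath_umbrella",
    "toy_fullpath_hysteresis",
    "toy_stripe_line_tension",
    "lifetime_recovery",
]


# --------------------------------------------------------------------------
# WHAM oracle: exact sampling from a known double-well free energy
# --------------------------------------------------------------------------

def doublewell_free_energy(a: float = 10.0) -> Callable[[np.ndarray], np.ndarray]:
    """G(x) = a (x^2 - 1)^2, the analytic double-well test profile (kJ/mol)."""
    return lambda x: a * (np.asarray(x) ** 2 - 1.0) ** 2


def sample_doublewell_windows(seed: int, a: float = 10.0, kappa: float = 5000.0,
                              n_windows: int = 20, n_samples: int = 5000,
                              lo: float = -0.6, hi: float = 0.6,
                              temperature: float = 310.0) -> List[UmbrellaWindow]:
    """Umbrella windows whose samples are drawn exactly (inverse-CDF on a fine
    grid) from the biased Boltzmann density exp(-(G + U_i)/kT).

    The default span follows the standard umbrella design rule: window
    spacing of ~2-3 thermal widths sqrt(kT/kappa) so adjacent histograms
    overlap (with kappa = 5000 kJ/mol the thermal width is 0.023, so 20
    windows cover about [-0.6, 0.6]).
    """
    rng = np.random.default_rng(seed)
    G = doublewell_free_energy(a)
    kT = KB * temperature
    centers = make_window_centers(lo, hi, count=n_windows)
    span = 6.0 * np.sqrt(kT / kappa)
    windows = []
    for c in centers:
        x = np.linspace(c - span, c + span, 20001)
        logp = -(G(x) + 0.5 * kappa * (x - c) ** 2) / kT
        p = np.exp(logp - logp.max())
        cdf = np.cumsum(p)
        cdf /= cdf[-1]
        u = rng.uniform(size=n_samples)
        samples = np.interp(u, cdf, x)
        windows.append(UmbrellaWindow(center=float(c), kappa=kappa,
                                      samples=samples, temperature=temperature))
    return windows


def wham_doublewell_rms(seed: int, n_bins: int = 120, min_count: int = 10,
                        **kwargs) -> Tuple[float, FreeEnergyProfile]:
    """Recover the double-well profile by WHAM and return the RMS deviation
    from the analytic form over the sampled range (mean-offset aligned).

    The sampled range is defined as bins holding at least ``min_count``
    samples in total; a bin visited by a single stray 5-sigma tail sample
    carries only shot noise, not information about G.
    """
    windows = sample_doublewell_windows(seed, **kwargs)
    profile = wham_solve(windows, n_bins=n_bins)
    G_true = doublewell_free_energy(kwargs.get("a", 10.0))(profile.grid)
    alls = np.concatenate([w.samples for w in windows])
    width = profile.grid[1] - profile.grid[0]
    edges = np.append(profile.grid - width / 2, profile.grid[-1] + width / 2)
    counts, _ = np.histogram(alls, bins=edges)
    mask = profile.sampled & (counts >= min_count)
    diff = profile.G[mask] - G_true[mask]
    diff -= diff.mean()
    return float(np.sqrt(np.mean(diff ** 2))), profile


# --------------------------------------------------------------------------
# toy-system construction
# --------------------------------------------------------------------------

#: Geometry used for toy-MD runs: bead sizes of the Cooke-style force field
#: (sigma = 0.6 nm) imply ~1.2 sigma^2 = 0.43 nm^2 per lipid in the fluid
#: phase and a thinner bilayer than the CV fixtures.
TOY_GEOMETRY = dict(area_per_lipid=0.43, leaflet_separation=0.7,
                    water_density=0.0, jitter=0.02)


def toy_bilayer_config(n_lipids: int = 36, seed: int = 0,
                       ff: Optional[ToyForceField] = None,
                       minimize_steps: int = 300) -> ParticleConfiguration:
    """A relaxed toy flat bilayer ready for dynamics."""
    ff = ff or ToyForceField()
    spec = GeometrySpec(n_lipids=n_lipids, seed=seed, **TOY_GEOMETRY)
    return minimize(build_flat_bilayer(spec), ff, n_steps=minimize_steps)


def toy_stripe_config(n_lipids: int = 60, seed: int = 0,
                      ff: Optional[ToyForceField] = None,
                      minimize_steps: int = 300) -> ParticleConfiguration:
    """A relaxed toy stripe (ribbon periodic along y, rims at the z ends)."""
    ff = ff or ToyForceField()
    # rim edge ~4 nm keeps the periodic rim longer than twice the
    # interaction cutoff even in the most compressed umbrella window
    spec = GeometrySpec(n_lipids=n_lipids, stripe=True, seed=seed,
                        rim_gap=3.0, normal_edge=8.5, rim_length=4.0,
                        **TOY_GEOMETRY)
    return minimize(build_stripe(spec), ff, n_steps=minimize_steps)


# --------------------------------------------------------------------------
# Full-Path umbrella pipeline on the toy bilayer
# --------------------------------------------------------------------------

@dataclass
class FullPathUmbrellaResult:
    profile: FreeEnergyProfile
    quad: QuadraticFit
    quad_err: float
    windows: List[UmbrellaWindow]
    cv_params: CVParams


def _fullpath_windows_from_frames(frames, series, centers, params, ff,
                                  settings, kappa, n_steps, sample_every,
                                  keep_fraction):
    from .free_energy import seed_windows

    cv = series["cv"].to_numpy()
    # a centre slightly beyond the pulled range is seeded from the closest
    # visited state; its own bias then pulls it the rest of the way
    lookup = np.clip(centers, cv.min(), cv.max())
    idx = seed_windows(cv, lookup)
    windows = []
    for w_i, (c, i) in enumerate(zip(centers, idx)):
        wset = replace(settings, seed=settings.seed + 1000 + w_i)
        samples, _ = run_window(frames[i], ff, wset, params, center=float(c),
                                kappa=kappa, n_steps=n_steps,
                                sample_every=sample_every,
                                keep_fraction=keep_fraction)
        windows.append(UmbrellaWindow(center=float(c), kappa=kappa,
                                      samples=samples,
                                      temperature=settings.temperature))
    return windows


def toy_fullpath_umbrella(seed: int = 0, n_lipids: int = 98,
                          cv_lo: float = 0.05, cv_hi: float = 0.85,
                          n_windows: int = 9, kappa: float = 300.0,
                          steer_kappa: float = 1500.0,
                          steer_steps: int = 18000, window_steps: int = 20000,
                          sample_every: int = 10, keep_fraction: float = 0.35,
                          reverse: bool = False,
                          config: Optional[ParticleConfiguration] = None,
                          params: Optional[CVParams] = None,
                          ff: Optional[ToyForceField] = None
                          ) -> FullPathUmbrellaResult:
    """Steer the Full-Path CV across the defect-opening range on a toy
    bilayer, seed umbrella windows from the pull, run them, and WHAM + fit.

    The toy range stops below the switching threshold: the defect regime
    (including the whole quadratic fit range CV <= 0.5) is what a small
    implicit-solvent membrane can traverse reversibly, and crossing into the
    expansion regime requires the large-pore fluctuations the method itself
    reports as rare below CV_radius ~ 0.85.

    With ``reverse=True`` the pull runs from cv_hi down to cv_lo (window
    seeding from a closing trajectory), which together with the forward run
    forms the hysteresis check.
    """
    ff = ff or ToyForceField()
    settings = SimulationSettings(seed=seed, timestep=0.02, friction=1.0)
    cfg = config if config is not None else toy_bilayer_config(n_lipids, seed, ff)
    if params is None:
        # R_cyl scaled to the toy membrane so that emptying the cylinder
        # costs a tolerable area strain (the full 1.2 nm cylinder of the
        # default parameters would displace ~20% of a small toy bilayer)
        params = CVParams(r_cyl=0.8)
        cal = calibrate_cv_eq([cfg], params)
        params = replace(params, cv_eq=cal.cv_eq)

    a, b = (cv_hi, cv_lo) if reverse else (cv_lo, cv_hi)
    pull_settings = replace(settings, seed=seed + 17)
    if reverse:
        # open the defect first so the closing pull starts from an open state
        frames_open, _ = steered_pull(cfg, ff, replace(settings, seed=seed + 29),
                                      params, cv_lo, cv_hi,
                                      kappa=steer_kappa, n_steps=steer_steps,
                                      sample_every=sample_every)
        cfg = frames_open[-1]
    frames, series = steered_pull(cfg, ff, pull_settings, params, a, b,
                                  kappa=steer_kappa, n_steps=steer_steps,
                                  sample_every=sample_every)
    centers = make_window_centers(cv_lo, cv_hi, count=n_windows)
    windows = _fullpath_windows_from_frames(
        frames, series, centers, params, ff, settings, kappa,
        window_steps, sample_every, keep_fraction=keep_fraction)
    profile = wham_solve(windows, n_bins=80)
    quad = fit_quadratic(profile, cv_max=0.5)
    quad_err = halves_error(
        windows, lambda ws: fit_quadratic(wham_solve(ws, n_bins=80),
                                          cv_max=0.5).k)
    return FullPathUmbrellaResult(profile=profile, quad=quad,
                                  quad_err=quad_err, windows=windows,
                                  cv_params=params)


def _halves_profile_band(windows: Sequence[UmbrellaWindow],
                         bins: np.ndarray) -> np.ndarray:
    """Per-bin halves error of the WHAM profile: half the |difference|
    between profiles solved from the first and second halves of every
    window's production samples (NaN where either half is unsampled)."""
    import warnings as _w

    halves = []
    for part in (0, 1):
        ws = []
        for w in windows:
            n = len(w.samples)
            s = w.samples[: n // 2] if part == 0 else w.samples[n // 2:]
            ws.append(UmbrellaWindow(w.center, w.kappa, s, w.temperature))
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            halves.append(wham_solve(ws, bins=bins, tol=1e-6))
    d = halves[0].G - halves[1].G
    d = d - np.nanmean(d)
    return np.abs(d) / 2.0


@dataclass
class HysteresisResult:
    forward: FullPathUmbrellaResult
    reverse: FullPathUmbrellaResult
    mean_abs_dG: float
    mean_band: float
    max_abs_dG: float
    k_gap: float
    k_err_combined: float


def toy_fullpath_hysteresis(seed: int = 0, **kwargs) -> HysteresisResult:
    """Forward vs reverse window seeding of the toy Full-Path umbrella.

    Profiles from opening- and closing-seeded windows are re-solved on a
    common grid and compared bin by bin (mean-offset aligned) against the
    combined per-bin halves-error band of the two runs; a well-behaved CV
    shows no hysteresis, i.e. the mean |dG| lies within the combined band.
    """
    fwd = toy_fullpath_umbrella(seed=seed, reverse=False, **kwargs)
    rev = toy_fullpath_umbrella(seed=seed, reverse=True, **kwargs)
    alls = np.concatenate([w.samples for ws in (fwd.windows, rev.windows)
                           for w in ws])
    bins = np.linspace(alls.min() - 1e-9, alls.max() + 1e-9, 81)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        pf = wham_solve(fwd.windows, bins=bins)
        pr = wham_solve(rev.windows, bins=bins)
    band = _halves_profile_band(fwd.windows, bins) + \
        _halves_profile_band(rev.windows, bins)
    common = pf.sampled & pr.sampled & np.isfinite(band)
    d = pf.G[common] - pr.G[common]
    d -= d.mean()
    return HysteresisResult(
        forward=fwd, reverse=rev,
        mean_abs_dG=float(np.mean(np.abs(d))),
        mean_band=float(np.mean(band[common])),
        max_abs_dG=float(np.max(np.abs(d))),
        k_gap=float(abs(fwd.quad.k - rev.quad.k)),
        k_err_combined=float(fwd.quad_err + rev.quad_err),
    )


# --------------------------------------------------------------------------
# Rapid pipeline on the toy stripe
# --------------------------------------------------------------------------

@dataclass
class RapidResult:
    gamma: LineTensionResult
    profile: FreeEnergyProfile
    windows: List[UmbrellaWindow]
    rim_L0: float


def toy_stripe_line_tension(seed: int = 0, n_lipids: int = 60,
                            n_windows: int = 11, kappa: float = 2000.0,
                            window_steps: int = 8000, sample_every: int = 10,
                            eps_scale: float = 1.0,
                            span: Tuple[float, float] = (-0.05, 0.12),
                            config: Optional[ParticleConfiguration] = None
                            ) -> RapidResult:
    """Umbrella sampling of the rim-axis box edge of a toy stripe and the
    linear line-tension fit (two rims).

    ``eps_scale`` scales the tail-tail attraction depth; line tension must
    grow with it (more cohesive membranes resist rim lengthening more).
    """
    ff = ToyForceField()
    ff = replace(ff, tail_attraction_eps=ff.tail_attraction_eps * eps_scale)
    cfg = config if config is not None else toy_stripe_config(n_lipids, seed, ff)
    L0 = float(cfg.box[1])
    centers = make_window_centers(L0 * (1 + span[0]), L0 * (1 + span[1]),
                                  count=n_windows)
    fb = StripeFlatBottomBias(BiasSpec(kind="flat_bottom", k_fb=1000.0,
                                       half_width=2.5), axis=0)
    windows = []
    for w_i, c in enumerate(centers):
        settings = SimulationSettings(seed=seed + 101 + w_i, timestep=0.02,
                                      friction=1.0, box_coupling="rim_mc",
                                      box_move_interval=5, box_move_step=0.015,
                                      rim_axis=1)
        rim = RimLengthBias(BiasSpec(kind="harmonic", center=float(c),
                                     kappa=kappa), rim_axis=1)
        out = run_langevin(cfg, ff, settings, biases=[fb, rim],
                           n_steps=window_steps, sample_every=sample_every,
                           recorders={"box_rim": lambda s: s.config.box[1]})
        series = out["series"]["box_rim"].to_numpy()
        keep = len(series) // 2
        windows.append(UmbrellaWindow(center=float(c), kappa=kappa,
                                      samples=series[-keep:],
                                      temperature=settings.temperature))
    profile = wham_solve(windows, n_bins=60)
    gamma = fit_line_tension_profile(profile, mode="rapid")
    err = halves_error(
        windows, lambda ws: fit_line_tension_profile(
            wham_solve(ws, n_bins=60), mode="rapid").gamma_pN)
    gamma.error = err
    return RapidResult(gamma=gamma, profile=profile, windows=windows, rim_L0=L0)


# --------------------------------------------------------------------------
# lifetime-recovery study
# --------------------------------------------------------------------------

def lifetime_recovery(seed: int = 0, n_replicates: int = 20,
                      sigma: float = 0.05, a0: float = 0.5, a1: float = 0.05,
                      a2: float = 120.0, t_max: float = 300.0,
                      n_points: int = 300) -> Tuple[float, np.ndarray]:
    """Generate noisy synthetic pore-state series from the tanh model and
    refit; returns (mean relative |A2 error|, per-replicate errors)."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_max, n_points)
    errors = []
    for _ in range(n_replicates):
        s = tanh_decay(t, a0, a1, a2) + rng.normal(0.0, sigma, size=t.shape)
        series = PoreStateSeries(times=t, s_values=s)
        _, _, a2_hat = fit_pore_lifetime(series)
        errors.append(abs(a2_hat - a2) / a2)
    errors = np.asarray(errors)
    return float(errors.mean()), errors
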