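"""Implicit-solvent bead-lipid Langevin dynamics.

A deliberately minimal Cooke-style model — three beads per lipid (head, tail,
terminal tail), WCA repulsion between all lipid beads, a broadened cosine
tail-tail attraction between beads of different lipids, FENE bonds and a
harmonic head-terminal straightening term — integrated with BAOAB Langevin
dynamics.  Solvent is implicit; any water particles present are frozen.  The
model exists so that biased sampling (steered pulls, umbrella windows,
rim-length box biasing) can be exercised end to end: it self-assembles
bilayers, supports pores and stripe rims, and gives the collective variables
something physical to pull on, without claiming thermodynamic accuracy for
any real lipid.

Units are GROMACS-style throughout: nm, ps, kJ/mol, amu; with these choices
the thermal energy at 310 K is kB*T = 2.577 kJ/mol.

Box-length biasing (the Rapid CV) is realised as Metropolis volume moves on
the rim-axis edge with affine particle rescaling; the acceptance rule carries
the N ln(L'/L) configurational-measure term so the sampled marginal of the
edge length is exactly proportional to Z(L) exp(-U_bias(L)/kT).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .cv_fullpath import CVParams, fullpath_cv
from .cv_rapid import BiasSpec, flat_bottom_bias, harmonic_bias
from .membranes import HEAD, WATER, ParticleConfiguration

__all__ = [
    "KB",
    "ToyForceField",
    "SimulationSettings",
    "ToyMDState",
    "Bias",
    "FullPathBias",
    "HarmonicTether",
    "StripeFlatBottomBias",
    "RimLengthBias",
    "energy_forces",
    "total_potential",
    "minimize",
    "initialize_state",
    "langevin_step",
    "run_langevin",
    "steered_pull",
    "run_window",
]

KB = 0.00831446  # kJ mol^-1 K^-1
_WCA_FACT = 2.0 ** (1.0 / 6.0)


@dataclass
class ToyForceField:
    """Cooke-style bead-lipid force field (reduced mapping: nm, kJ/mol).

    bead_diameter        tail bead diameter sigma, nm (heads use 0.95 sigma)
    bond_stiffness       FENE spring constant, kJ mol^-1 nm^-2
    bond_length          FENE divergence length r_inf, nm
    bend_stiffness       harmonic head-terminal straightening constant,
                         kJ mol^-1 nm^-2 (rest distance 4 sigma)
    tail_attraction_eps  depth of the broadened tail-tail attraction, kJ/mol
    tail_attraction_range  attraction decay width w_c, nm
    repulsion_eps        WCA energy scale, kJ/mol
    """

    # kB*T at 310 K is 2.577 kJ/mol; eps = 2.3 puts kT/eps ~ 1.12, inside the
    # fluid-bilayer window of this class of models (cohesive but not gelled)
    bead_diameter: float = 0.6
    bond_stiffness: float = 216.0
    bond_length: float = 0.9
    bend_stiffness: float = 72.0
    tail_attraction_eps: float = 2.3
    tail_attraction_range: float = 0.96
    repulsion_eps: float = 2.3
    head_factor: float = 0.95
    overlap_floor_factor: float = 0.2

    def __post_init__(self) -> None:
        if self.tail_attraction_eps < 0:
            raise ValueError("tail_attraction_eps must be >= 0")
        if min(self.bead_diameter, self.bond_stiffness, self.bond_length,
               self.bend_stiffness, self.tail_attraction_range,
               self.repulsion_eps) <= 0:
            raise ValueError("force-field scales must be positive")


@dataclass
class SimulationSettings:
    """Langevin run settings.

    temperature   K (default 310)
    timestep      ps
    friction      1/ps
    seed          master RNG seed (window i of a protocol uses seed + i)
    n_steps       default step count for run helpers
    mass          bead mass, amu
    box_coupling  "off" or "rim_mc" (Metropolis moves on the rim edge)
    box_move_interval  steps between volume-move attempts
    box_move_step      proposal width for the rim edge, nm
    rim_axis      axis index of the biased rim edge (default y)
    """

    temperature: float = 310.0
    timestep: float = 0.02
    friction: float = 1.0
    seed: int = 0
    n_steps: int = 1000
    mass: float = 100.0
    box_coupling: str = "off"
    box_move_interval: int = 10
    box_move_step: float = 0.02
    rim_axis: int = 1

    def __post_init__(self) -> None:
        if self.timestep <= 0 or self.temperature <= 0 or self.mass <= 0:
            raise ValueError("timestep, temperature and mass must be positive")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")
        if self.box_coupling not in ("off", "rim_mc"):
            raise ValueError("box_coupling must be 'off' or 'rim_mc'")

    @property
    def kT(self) -> float:
        return KB * self.temperature


# --------------------------------------------------------------------------
# potential terms
# --------------------------------------------------------------------------

@njit(cache=True)
def _nonbonded_kernel(pos, box, periodic, species, lipid, sigma, head_factor,
                      eps_rep, eps_att, wc, forces):
    """WCA repulsion between all lipid beads + broadened inter-lipid tail
    attraction.  Returns (energy, min inter-particle distance)."""
    n = pos.shape[0]
    energy = 0.0
    min_d = 1.0e18
    for i in range(n - 1):
        if species[i] == 3:
            continue
        for j in range(i + 1, n):
            if species[j] == 3:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if periodic[0]:
                dx -= box[0] * np.rint(dx / box[0])
            if periodic[1]:
                dy -= box[1] * np.rint(dy / box[1])
            if periodic[2]:
                dz -= box[2] * np.rint(dz / box[2])
            r2 = dx * dx + dy * dy + dz * dz
            s = sigma
            if species[i] == 0 or species[j] == 0:
                s = sigma * head_factor
            rc_wca = 1.122462048309373 * s
            tails = (species[i] >= 1 and species[j] >= 1
                     and lipid[i] != lipid[j])
            cutoff = rc_wca + wc if tails else rc_wca
            if r2 >= cutoff * cutoff:
                continue
            r = np.sqrt(r2)
            if r < min_d:
                min_d = r
            dudr = 0.0
            if r < rc_wca:
                sr2 = (s / r) ** 2
                sr6 = sr2 * sr2 * sr2
                sr12 = sr6 * sr6
                energy += 4.0 * eps_rep * (sr12 - sr6) + eps_rep
                dudr += 4.0 * eps_rep * (-12.0 * sr12 + 6.0 * sr6) / r
            if tails:
                if r < rc_wca:
                    energy += -eps_att
                else:
                    arg = np.pi * (r - rc_wca) / (2.0 * wc)
                    c = np.cos(arg)
                    energy += -eps_att * c * c
                    dudr += eps_att * (np.pi / (2.0 * wc)) * np.sin(2.0 * arg)
            fr = -dudr / r
            forces[i, 0] += fr * dx
            forces[i, 1] += fr * dy
            forces[i, 2] += fr * dz
            forces[j, 0] -= fr * dx
            forces[j, 1] -= fr * dy
            forces[j, 2] -= fr * dz
    return energy, min_d


def _topology(config: ParticleConfiguration):
    """FENE bond pairs (head-tail, tail-terminal chains) and head-terminal
    straightening pairs, derived from lipid ids and roles."""
    bonds = []
    bends = []
    for lid in range(config.n_lipids):
        idx = np.where(config.lipid_ids == lid)[0]
        roles = config.roles[idx]
        head = idx[roles == HEAD]
        tails = idx[roles == 1]
        term = idx[roles == 2]
        if len(head) != 1 or len(term) != 1 or len(tails) < 1:
            raise ValueError(f"lipid {lid} is not a head-tail...-terminal chain")
        chain = [head[0], *tails.tolist(), term[0]]
        for a, b in zip(chain[:-1], chain[1:]):
            bonds.append((a, b))
        bends.append((head[0], term[0]))
    return (np.array(bonds, dtype=np.int64).reshape(-1, 2),
            np.array(bends, dtype=np.int64).reshape(-1, 2))


def _min_image(vec: np.ndarray, box: np.ndarray, periodic: np.ndarray) -> np.ndarray:
    for ax in range(3):
        if periodic[ax]:
            vec[..., ax] -= box[ax] * np.round(vec[..., ax] / box[ax])
    return vec


def energy_forces(config: ParticleConfiguration, ff: ToyForceField,
                  topology=None) -> Tuple[float, np.ndarray]:
    """Total potential energy (kJ/mol) and exact per-particle forces.

    Sum of WCA repulsion, broadened inter-lipid tail attraction, FENE bonds
    and the harmonic straightening term; minimum-image periodic.  Raises on
    particle overlap below ``overlap_floor_factor * bead_diameter`` and on a
    FENE bond stretched to its divergence length (both signal a blow-up).
    """
    pos = np.ascontiguousarray(config.positions)
    forces = np.zeros_like(pos)
    e_nb, min_d = _nonbonded_kernel(
        pos, config.box, config.periodic.astype(np.int8),
        config.roles.astype(np.int64), config.lipid_ids.astype(np.int64),
        ff.bead_diameter, ff.head_factor, ff.repulsion_eps,
        ff.tail_attraction_eps, ff.tail_attraction_range, forces)
    if min_d < ff.overlap_floor_factor * ff.bead_diameter:
        raise ValueError(f"particle overlap: min distance {min_d:.4f} nm")
    energy = e_nb

    bonds, bends = _topology(config) if topology is None else topology
    if len(bonds):
        dvec = _min_image(pos[bonds[:, 0]] - pos[bonds[:, 1]],
                          config.box, config.periodic)
        r = np.linalg.norm(dvec, axis=1)
        x2 = (r / ff.bond_length) ** 2
        if np.any(x2 >= 1.0):
            raise ValueError("FENE bond stretched beyond its divergence length")
        energy += float(-0.5 * ff.bond_stiffness * ff.bond_length ** 2
                        * np.log(1.0 - x2).sum())
        dudr = ff.bond_stiffness * r / (1.0 - x2)
        fvec = (-dudr / r)[:, None] * dvec
        np.add.at(forces, bonds[:, 0], fvec)
        np.add.at(forces, bonds[:, 1], -fvec)
    if len(bends):
        r0 = 4.0 * ff.bead_diameter
        dvec = _min_image(pos[bends[:, 0]] - pos[bends[:, 1]],
                          config.box, config.periodic)
        r = np.linalg.norm(dvec, axis=1)
        energy += float(0.5 * ff.bend_stiffness * ((r - r0) ** 2).sum())
        dudr = ff.bend_stiffness * (r - r0)
        fvec = (-dudr / r)[:, None] * dvec
        np.add.at(forces, bends[:, 0], fvec)
        np.add.at(forces, bends[:, 1], -fvec)
    forces[config.roles == WATER] = 0.0
    return float(energy), forces


# --------------------------------------------------------------------------
# biases
# --------------------------------------------------------------------------

class Bias:
    """A bias contributes energy and per-particle forces; box biases add an
    explicit edge-length term used by the Metropolis volume move."""

    def energy_forces(self, config: ParticleConfiguration,
                      time: float) -> Tuple[float, np.ndarray]:
        return 0.0, np.zeros_like(config.positions)

    def box_energy(self, box: np.ndarray, time: float) -> float:
        return 0.0


class FullPathBias(Bias):
    """(Moving-)harmonic restraint on the Full-Path CV; the force is the
    chain rule through the exact per-particle CV gradient."""

    def __init__(self, params: CVParams, spec: BiasSpec):
        if spec.kind not in ("harmonic", "moving_harmonic"):
            raise ValueError("FullPathBias needs a harmonic BiasSpec")
        self.params = params
        self.spec = spec
        self.last_cv = None

    def energy_forces(self, config, time):
        cvv = fullpath_cv(config, self.params)
        self.last_cv = cvv
        u, dudcv = harmonic_bias(cvv.value, self.spec, time)
        return u, -dudcv * cvv.gradient


class HarmonicTether(Bias):
    """Harmonic position restraint on selected particles (testing aid)."""

    def __init__(self, indices: Sequence[int], kappa: float,
                 reference: np.ndarray):
        self.indices = np.asarray(indices, dtype=int)
        self.kappa = float(kappa)
        self.reference = np.atleast_2d(np.asarray(reference, dtype=float))

    def energy_forces(self, config, time):
        delta = config.positions[self.indices] - self.reference
        forces = np.zeros_like(config.positions)
        forces[self.indices] = -self.kappa * delta
        return float(0.5 * self.kappa * (delta ** 2).sum()), forces


class StripeFlatBottomBias(Bias):
    """Flat-bottom restraint on head beads along the membrane normal,
    referenced to the instantaneous mean head coordinate (the stripe centre
    of mass proxy); keeps the stripe from drifting/rotating into its
    periodic image.  The reference's dependence on the positions is included
    in the force, so the bias force is an exact gradient."""

    def __init__(self, spec: BiasSpec, axis: int = 0):
        if spec.kind != "flat_bottom":
            raise ValueError("StripeFlatBottomBias needs a flat_bottom BiasSpec")
        self.spec = spec
        self.axis = axis

    def energy_forces(self, config, time):
        heads = np.where(config.roles == HEAD)[0]
        x = config.positions[heads, self.axis]
        ref = x.mean()
        energy = 0.0
        f = np.zeros(len(heads))
        for k, xi in enumerate(x):
            u, force = flat_bottom_bias(xi, ref, self.spec)
            energy += u
            f[k] = force
        forces = np.zeros_like(config.positions)
        # the reference depends on the positions: d(ref)/dx_j = 1/N
        forces[heads, self.axis] = f - f.sum() / len(heads)
        return float(energy), forces


class RimLengthBias(Bias):
    """Harmonic umbrella on the rim-axis box edge (the Rapid CV); applied
    through the Metropolis volume move, not as a particle force."""

    def __init__(self, spec: BiasSpec, rim_axis: int = 1):
        if spec.kind not in ("harmonic", "moving_harmonic"):
            raise ValueError("RimLengthBias needs a harmonic BiasSpec")
        self.spec = spec
        self.rim_axis = rim_axis

    def box_energy(self, box, time):
        u, _ = harmonic_bias(float(box[self.rim_axis]), self.spec, time)
        return u


def total_potential(config: ParticleConfiguration, ff: ToyForceField,
                    biases: Sequence[Bias] = (), time: float = 0.0,
                    topology=None) -> float:
    """Force-field energy plus all bias energies (particle and box terms)."""
    e, _ = energy_forces(config, ff, topology=topology)
    for b in biases:
        eb, _ = b.energy_forces(config, time)
        e += eb + b.box_energy(config.box, time)
    return e


# --------------------------------------------------------------------------
# integration
# --------------------------------------------------------------------------

@dataclass
class ToyMDState:
    """Mutable state advanced by :func:`langevin_step`."""

    config: ParticleConfiguration
    velocities: np.ndarray
    rng: np.random.Generator
    step: int = 0
    time: float = 0.0
    forces: Optional[np.ndarray] = None
    topology: Optional[tuple] = None
    n_box_accept: int = 0
    n_box_try: int = 0


def minimize(config: ParticleConfiguration, ff: ToyForceField,
             n_steps: int = 200, max_disp: float = 0.02) -> ParticleConfiguration:
    """Displacement-capped steepest descent to relax builder geometry before
    dynamics (bead spacings of the builders differ from the force-field
    minima)."""
    out = config.copy()
    topo = _topology(out)
    gamma = 2e-4  # nm^2 mol kJ^-1 per step; displacement capped below
    for _ in range(n_steps):
        _, forces = energy_forces(out, ff, topology=topo)
        norm = np.linalg.norm(forces, axis=1, keepdims=True)
        step_len = np.minimum(gamma * norm, max_disp)
        out.positions += forces / np.maximum(norm, 1e-12) * step_len
        out = out.wrapped()
    return out


def initialize_state(config: ParticleConfiguration, ff: ToyForceField,
                     settings: SimulationSettings) -> ToyMDState:
    """Thermalise velocities and cache forces/topology for stepping."""
    rng = np.random.default_rng(settings.seed)
    vel = rng.normal(0.0, np.sqrt(settings.kT / settings.mass),
                     size=config.positions.shape)
    vel[config.roles == WATER] = 0.0
    state = ToyMDState(config=config.copy(), velocities=vel, rng=rng)
    state.topology = _topology(state.config)
    return state


def _total_forces(state: ToyMDState, ff: ToyForceField,
                  biases: Sequence[Bias]) -> Tuple[float, np.ndarray]:
    e, f = energy_forces(state.config, ff, topology=state.topology)
    for b in biases:
        eb, fb = b.energy_forces(state.config, state.time)
        e += eb
        f += fb
    return e, f


def _attempt_box_move(state: ToyMDState, ff: ToyForceField,
                      biases: Sequence[Bias],
                      settings: SimulationSettings) -> None:
    ax = settings.rim_axis
    cfg = state.config
    L = cfg.box[ax]
    dL = state.rng.normal(0.0, settings.box_move_step)
    Lp = L + dL
    if Lp <= 0.5 * L:
        return
    state.n_box_try += 1
    e_old = total_potential(cfg, ff, biases, state.time, topology=state.topology)
    trial = cfg.copy()
    trial.box[ax] = Lp
    trial.positions[:, ax] *= Lp / L
    try:
        e_new = total_potential(trial, ff, biases, state.time,
                                topology=state.topology)
    except ValueError:
        return  # overlap in the trial state: reject
    n_mobile = int(np.sum(cfg.roles != WATER))
    log_acc = -(e_new - e_old) / settings.kT + n_mobile * np.log(Lp / L)
    if np.log(state.rng.uniform()) < log_acc:
        cfg.box[ax] = Lp
        cfg.positions[:, ax] *= Lp / L
        state.forces = None  # stale after rescale
        state.n_box_accept += 1


def langevin_step(state: ToyMDState, ff: ToyForceField,
                  settings: SimulationSettings,
                  biases: Sequence[Bias] = ()) -> ToyMDState:
    """One BAOAB Langevin step (plus a periodic Metropolis box move when
    ``settings.box_coupling == 'rim_mc'``).

    Deterministic for a fixed seed; raises on non-finite coordinates or on
    the overlap/FENE guards in the force evaluation.
    """
    cfg = state.config
    dt = settings.timestep
    m = settings.mass
    mobile = cfg.roles != WATER
    if state.topology is None:
        state.topology = _topology(cfg)
    if state.forces is None:
        _, state.forces = _total_forces(state, ff, biases)

    v = state.velocities
    v[mobile] += 0.5 * dt * state.forces[mobile] / m
    cfg.positions[mobile] += 0.5 * dt * v[mobile]
    if settings.friction > 0:
        c1 = np.exp(-settings.friction * dt)
        c2 = np.sqrt((1.0 - c1 * c1) * settings.kT / m)
        noise = state.rng.normal(size=v.shape)
        v[mobile] = c1 * v[mobile] + c2 * noise[mobile]
    cfg.positions[mobile] += 0.5 * dt * v[mobile]
    for axis in range(3):
        if cfg.periodic[axis]:
            cfg.positions[:, axis] %= cfg.box[axis]
    if not np.all(np.isfinite(cfg.positions)):
        raise ValueError("non-finite coordinates: integration blew up")
    state.time += dt
    _, state.forces = _total_forces(state, ff, biases)
    v[mobile] += 0.5 * dt * state.forces[mobile] / m
    state.step += 1

    if (settings.box_coupling == "rim_mc"
            and state.step % settings.box_move_interval == 0):
        _attempt_box_move(state, ff, biases, settings)
        if state.forces is None:
            _, state.forces = _total_forces(state, ff, biases)
    return state


def run_langevin(config: ParticleConfiguration, ff: ToyForceField,
                 settings: SimulationSettings, biases: Sequence[Bias] = (),
                 n_steps: Optional[int] = None, sample_every: int = 50,
                 recorders: Optional[dict] = None,
                 keep_frames: bool = False):
    """Integrate and record observables.

    ``recorders`` maps column name -> callable(state) -> float; the returned
    dict has 'series' (pandas-ready dict of numpy columns, always containing
    'time') and optionally 'frames'.
    """
    import pandas as pd

    state = initialize_state(config, ff, settings)
    n = settings.n_steps if n_steps is None else n_steps
    cols: dict = {"time": []}
    for name in (recorders or {}):
        cols[name] = []
    frames: List[ParticleConfiguration] = []
    for _ in range(n):
        langevin_step(state, ff, settings, biases)
        if state.step % sample_every == 0:
            cols["time"].append(state.time)
            for name, fn in (recorders or {}).items():
                cols[name].append(float(fn(state)))
            if keep_frames:
                frames.append(state.config.copy())
    series = pd.DataFrame({k: np.asarray(v) for k, v in cols.items()})
    return {"series": series, "frames": frames, "state": state}


def steered_pull(config: ParticleConfiguration, ff: ToyForceField,
                 settings: SimulationSettings, params: CVParams,
                 cv_start: float, cv_end: float, kappa: float,
                 n_steps: int, sample_every: int = 50,
                 extra_biases: Sequence[Bias] = ()):
    """Moving-harmonic pull of the Full-Path CV from cv_start to cv_end.

    Returns frames (for window seeding) and the recorded CV series with
    components, COLVAR-style columns: time, cv, cv_cyl, cv_radius, s1, s2.
    """
    t_total = n_steps * settings.timestep
    spec = BiasSpec(kind="moving_harmonic", kappa=kappa,
                    schedule=(cv_start, cv_end, t_total))
    bias = FullPathBias(params, spec)

    def rec(attr):
        return lambda state: getattr(bias.last_cv, attr)

    out = run_langevin(config, ff, settings,
                       biases=[bias, *extra_biases], n_steps=n_steps,
                       sample_every=sample_every,
                       recorders={"cv": rec("value"), "cv_cyl": rec("cv_cyl"),
                                  "cv_radius": rec("cv_radius"),
                                  "s1": rec("s1"), "s2": rec("s2")},
                       keep_frames=True)
    return out["frames"], out["series"]


def run_window(config: ParticleConfiguration, ff: ToyForceField,
               settings: SimulationSettings, params: CVParams,
               center: float, kappa: float, n_steps: int,
               sample_every: int = 20, keep_fraction: float = 0.25,
               extra_biases: Sequence[Bias] = ()):
    """Fixed-centre umbrella window on the Full-Path CV.

    The first (1 - keep_fraction) of the samples is discarded as
    equilibration (production-discard policy expressed as a fraction);
    returns the retained CV sample array and the full series.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    bias = FullPathBias(params, BiasSpec(kind="harmonic", center=center,
                                         kappa=kappa))
    out = run_langevin(config, ff, settings, biases=[bias, *extra_biases],
                       n_steps=n_steps, sample_every=sample_every,
                       recorders={"cv": lambda s: bias.last_cv.value})
    series = out["series"]
    n_keep = int(np.ceil(len(series) * keep_fraction))
    samples = series["cv"].to_numpy()[len(series) - n_keep:]
    return samples, series
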