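"""Slice-based pore-state observable s(t), pore-lifetime fitting, and the
distal-tail-density observable.

The membrane is split into N_S slices of equal width along the normal (z),
centred on the lipid centre of geometry.  Water occupancy per slice is a
Gaussian-weighted count (peak-normalised, truncated at the slice boundaries)
so an atom at the slice centre counts as one molecule; a Heaviside step with
threshold one molecule classifies each slice wet/dry, and s is the wet
fraction.  s = 1 while a continuous transmembrane water thread exists and
decays to ~0.25 (the solvent-slab slices) after pore closure; the closure
time is the inflection point A2 of a hyperbolic-tangent fit

    s(t) ~ A0 * (1 - tanh(A1 * (t - A2))).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .membranes import TERMINAL_TAIL, ParticleConfiguration

__all__ = [
    "SliceSpec",
    "PoreStateSeries",
    "slice_water_counts",
    "pore_state_value",
    "pore_state_series",
    "tanh_decay",
    "fit_pore_lifetime",
    "distal_tail_density",
]


@dataclass
class SliceSpec:
    """Slice geometry for the pore-state observable.

    interval            [z_lo, z_hi] around the bilayer centre of geometry, nm
    width               slice width, nm ((z_hi - z_lo)/width must be integer;
                        defaults give N_S = 17)
    kernel_bandwidth    Gaussian weight bandwidth, nm
    occupancy_threshold weighted molecules needed for a slice to count as wet
    """

    interval: Tuple[float, float] = (-2.125, 2.125)
    width: float = 0.25
    kernel_bandwidth: float = 0.1
    occupancy_threshold: float = 1.0

    def __post_init__(self) -> None:
        z_lo, z_hi = self.interval
        if self.width <= 0 or z_hi <= z_lo:
            raise ValueError("width must be > 0 and interval non-empty")
        n = (z_hi - z_lo) / self.width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("interval length must be an integer multiple of width")
        if self.kernel_bandwidth <= 0:
            raise ValueError("kernel_bandwidth must be positive")

    @property
    def n_slices(self) -> int:
        z_lo, z_hi = self.interval
        return int(round((z_hi - z_lo) / self.width))

    @property
    def centers(self) -> np.ndarray:
        z_lo, _ = self.interval
        return z_lo + self.width * (np.arange(self.n_slices) + 0.5)


@dataclass
class PoreStateSeries:
    """Time series of the pore state with optional occupancy and fit fields."""

    times: np.ndarray
    s_values: np.ndarray
    occupancy: Optional[np.ndarray] = None  # (n_frames, N_S)
    fit_A0: Optional[float] = None
    fit_A1: Optional[float] = None
    fit_A2: Optional[float] = None
    fit_perr: Optional[np.ndarray] = None


def slice_water_counts(config: ParticleConfiguration, spec: SliceSpec) -> np.ndarray:
    """Gaussian-weighted water count per slice.

    Slices are positioned relative to the lipid centre of geometry along z.
    Each water particle contributes exp(-dz^2 / (2 bw^2)) to the slice whose
    boundaries contain it (dz measured from that slice's centre); the weight
    is truncated at the boundaries, so a particle contributes to exactly one
    slice and a particle at a slice centre counts as one molecule.
    """
    if not config.lipid_mask.any():
        raise ValueError("configuration has no lipids to centre the slices on")
    z_cog = float(config.positions[config.lipid_mask][:, 2].mean())
    wmask = config.water_mask
    counts = np.zeros(spec.n_slices)
    if not wmask.any():
        return counts
    dz = config.positions[wmask][:, 2] - z_cog
    if config.periodic[2]:
        L = config.box[2]
        dz -= L * np.round(dz / L)
    z_lo, z_hi = spec.interval
    idx = np.floor((dz - z_lo) / spec.width).astype(int)
    ok = (idx >= 0) & (idx < spec.n_slices) & (dz >= z_lo) & (dz < z_hi)
    off = dz[ok] - spec.centers[idx[ok]]
    w = np.exp(-0.5 * (off / spec.kernel_bandwidth) ** 2)
    np.add.at(counts, idx[ok], w)
    return counts


def pore_state_value(counts: Sequence[float], spec: SliceSpec) -> float:
    """Pore state s = wet-slice fraction.

    A slice is wet when its weighted count reaches the occupancy threshold;
    the Heaviside step takes the boundary as wet (a count exactly at the
    threshold counts).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (spec.n_slices,):
        raise ValueError(f"expected {spec.n_slices} slice counts, got {counts.shape}")
    wet = counts >= spec.occupancy_threshold
    return float(wet.mean())


def pore_state_series(frames: Iterable[ParticleConfiguration],
                      spec: SliceSpec,
                      times: Optional[Sequence[float]] = None) -> PoreStateSeries:
    """Evaluate s(t) over a trajectory."""
    occ = np.array([slice_water_counts(f, spec) for f in frames])
    if occ.size == 0:
        raise ValueError("empty trajectory")
    s = (occ >= spec.occupancy_threshold).mean(axis=1)
    t = np.arange(len(s), dtype=float) if times is None else np.asarray(times, float)
    return PoreStateSeries(times=t, s_values=s, occupancy=occ)


def tanh_decay(t, a0, a1, a2):
    """The three-parameter sigmoidal decay s(t) = A0 (1 - tanh(A1 (t - A2)))."""
    return a0 * (1.0 - np.tanh(a1 * (t - a2)))


def fit_pore_lifetime(series: PoreStateSeries) -> Tuple[float, float, float]:
    """Least-squares fit of s(t) to the tanh decay; A2 is the pore lifetime.

    A2 is initialised at the first time s drops below half its initial
    plateau.  Raises if s never decreases (no closure event) or the optimiser
    fails.  Fitted parameters are stored on the series; the covariance-based
    one-sigma uncertainties are returned via the series as well.
    """
    t = np.asarray(series.times, dtype=float)
    s = np.asarray(series.s_values, dtype=float)
    if len(t) < 10:
        raise ValueError("need at least 10 points to fit a lifetime")
    plateau = s[: max(3, len(s) // 20)].mean()
    below = np.nonzero(s < 0.5 * plateau)[0]
    if plateau <= 0 or below.size == 0 or np.ptp(s) < 1e-12:
        raise ValueError("series shows no closure (s never drops below half plateau)")
    a2_0 = t[below[0]]
    span = max(t[-1] - t[0], 1e-12)
    p0 = (plateau / 2.0, 10.0 / span, a2_0)
    try:
        popt, pcov = curve_fit(tanh_decay, t, s, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - optimizer pathologies
        raise ValueError(f"lifetime fit did not converge: {exc}") from exc
    a0, a1, a2 = (float(v) for v in popt)
    series.fit_A0, series.fit_A1, series.fit_A2 = a0, a1, a2
    series.fit_perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    return a0, a1, a2


def distal_tail_density(frames: Iterable[ParticleConfiguration],
                        probe_radius: float = 0.5) -> float:
    """Time-averaged number density (nm^-3) of terminal-tail beads in the
    membrane-core region |z - midplane| < probe_radius.

    The midplane is the per-frame lipid centre of geometry.  A depletion of
    this density signals a hydrophobic defect; across lipid types it
    correlates with pore lifetime, which motivates building the defect CV on
    lipid-tail beads.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    densities = []
    for f in frames:
        if not f.lipid_mask.any():
            raise ValueError("frame has no lipids")
        zc = f.positions[f.lipid_mask][:, 2].mean()
        term = f.roles == TERMINAL_TAIL
        dz = f.positions[term][:, 2] - zc
        if f.periodic[2]:
            L = f.box[2]
            dz -= L * np.round(dz / L)
        n_in = int(np.sum(np.abs(dz) < probe_radius))
        vol = f.box[0] * f.box[1] * 2 * probe_radius
        densities.append(n_in / vol)
    if not densities:
        raise ValueError("empty trajectory")
    return float(np.mean(densities))
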