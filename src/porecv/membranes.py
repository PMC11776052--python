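"""Synthetic membrane-like particle configurations.

Deterministic, seeded builders for the three system geometries used throughout
the package: a flat bilayer, a bilayer with a cylindrical pore carrying a
transmembrane water column, and a lipid stripe (bilayer ribbon) with two
head-capped rims.  The builders produce geometry, not chemistry: each lipid is
three beads (head, tail, terminal tail) and water is a point particle.  These
configurations serve both as analysis fixtures for the collective variables and
as starting states for the implicit-solvent toy dynamics engine.

Coordinate conventions: lengths in nm, right-handed axes, membrane normal along
z for bilayers and along x for stripes (the rim axis of a stripe is y).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "HEAD",
    "TAIL",
    "TERMINAL_TAIL",
    "WATER",
    "ROLE_NAMES",
    "ROLE_CODES",
    "ParticleConfiguration",
    "GeometrySpec",
    "build_flat_bilayer",
    "build_pore_bilayer",
    "build_stripe",
    "recenter_lipids",
]

# Role codes.  Atom-name encodings (H/T/TT/W) live in porecv.io.
HEAD = 0
TAIL = 1
TERMINAL_TAIL = 2
WATER = 3

ROLE_NAMES = {HEAD: "head", TAIL: "tail", TERMINAL_TAIL: "terminal_tail", WATER: "water"}
ROLE_CODES = {v: k for k, v in ROLE_NAMES.items()}

# Intra-lipid bead spacing along the lipid axis (nm).
BEAD_SPACING = 0.5
# Lateral jitter applied to lipid grid positions (nm); keeps fixtures from
# being pathologically degenerate while preserving construction symmetry of
# the mean structure.
DEFAULT_JITTER = 0.03


@dataclass
class ParticleConfiguration:
    """A particle system: positions, per-particle roles, lipid membership, box.

    positions : (N, 3) float array, nm
    roles     : (N,) int array with codes HEAD/TAIL/TERMINAL_TAIL/WATER
    lipid_ids : (N,) int array; consecutive ids starting at 0, -1 for water
    box       : (3,) float array of edge lengths, nm (orthorhombic)
    periodic  : (3,) bool array
    """

    positions: np.ndarray
    roles: np.ndarray
    lipid_ids: np.ndarray
    box: np.ndarray
    periodic: np.ndarray = field(default_factory=lambda: np.ones(3, dtype=bool))

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.roles = np.asarray(self.roles, dtype=int)
        self.lipid_ids = np.asarray(self.lipid_ids, dtype=int)
        self.box = np.asarray(self.box, dtype=float)
        self.periodic = np.asarray(self.periodic, dtype=bool)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        n = len(self.positions)
        if len(self.roles) != n or len(self.lipid_ids) != n:
            raise ValueError("roles/lipid_ids length mismatch with positions")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive edge lengths")

    # -- selections ---------------------------------------------------------
    @property
    def n_particles(self) -> int:
        return len(self.positions)

    @property
    def n_lipids(self) -> int:
        ids = self.lipid_ids[self.lipid_ids >= 0]
        return 0 if ids.size == 0 else int(ids.max()) + 1

    def select(self, *roles: int) -> np.ndarray:
        """Boolean mask of particles whose role is in `roles`."""
        return np.isin(self.roles, roles)

    @property
    def tail_mask(self) -> np.ndarray:
        """Lipid-tail beads (tail + terminal tail), the CV selection."""
        return self.select(TAIL, TERMINAL_TAIL)

    @property
    def water_mask(self) -> np.ndarray:
        return self.select(WATER)

    @property
    def lipid_mask(self) -> np.ndarray:
        return self.lipid_ids >= 0

    def copy(self) -> "ParticleConfiguration":
        return ParticleConfiguration(
            self.positions.copy(), self.roles.copy(), self.lipid_ids.copy(),
            self.box.copy(), self.periodic.copy())

    def wrapped(self) -> "ParticleConfiguration":
        """Copy with all coordinates wrapped into the primary box [0, L)."""
        out = self.copy()
        for ax in range(3):
            if self.periodic[ax]:
                out.positions[:, ax] %= self.box[ax]
        return out

    def validate_lipids(self) -> None:
        """Check that every lipid id owns exactly one head, >=1 tail and one
        terminal tail, and that roles partition the particle set."""
        if not np.all((self.roles >= 0) & (self.roles <= 3)):
            raise ValueError("unknown role code present")
        if np.any((self.roles == WATER) != (self.lipid_ids < 0)):
            raise ValueError("water particles must carry lipid_id -1 and vice versa")
        for lid in range(self.n_lipids):
            sel = self.lipid_ids == lid
            r = self.roles[sel]
            if np.sum(r == HEAD) != 1:
                raise ValueError(f"lipid {lid}: expected exactly one head bead")
            if np.sum(r == TAIL) < 1:
                raise ValueError(f"lipid {lid}: expected at least one tail bead")
            if np.sum(r == TERMINAL_TAIL) != 1:
                raise ValueError(f"lipid {lid}: expected exactly one terminal tail bead")


@dataclass
class GeometrySpec:
    """Parameters for the synthetic geometry builders.

    n_lipids           total lipid count (split equally between leaflets)
    area_per_lipid     nm^2 of membrane plane per lipid
    leaflet_separation gap between the terminal-tail planes of the two
                       leaflets, nm
    pore_radius        nm; 0 means no pore
    stripe             build a ribbon with two rims instead of a bilayer
    water_density      water particles per nm^3 used to fill solvent regions
    seed               RNG seed; identical spec+seed gives identical output
    rim_gap            stripe only: minimum rim-rim distance through the
                       non-periodic z boundary, nm (must be >= 2)
    normal_edge        stripe only: box edge along the membrane normal (x), nm
    rim_length         stripe only: requested rim (y) edge, nm; None picks a
                       near-square ribbon
    jitter             lateral grid jitter amplitude, nm
    water_pad          solvent slab thickness beyond the head planes for
                       bilayers, nm
    """

    n_lipids: int = 200
    area_per_lipid: float = 0.64
    leaflet_separation: float = 1.0
    pore_radius: float = 0.0
    stripe: bool = False
    water_density: float = 8.0
    seed: int = 0
    rim_gap: float = 3.0
    normal_edge: float = 8.5
    rim_length: Optional[float] = None
    jitter: float = DEFAULT_JITTER
    water_pad: float = 2.0

    def __post_init__(self) -> None:
        if self.n_lipids <= 0 or self.n_lipids % 2:
            raise ValueError("n_lipids must be positive and even (equal leaflets)")
        if self.area_per_lipid <= 0 or self.leaflet_separation <= 0:
            raise ValueError("area_per_lipid and leaflet_separation must be positive")
        if self.pore_radius < 0:
            raise ValueError("pore_radius must be >= 0")
        if self.water_density < 0:
            raise ValueError("water_density must be >= 0")
        if self.water_pad < 0 or self.jitter < 0:
            raise ValueError("water_pad and jitter must be >= 0")


def _grid_factorization(n: int) -> tuple[int, int]:
    """Most-square factorization n = nx * ny with nx <= ny."""
    if n <= 0:
        raise ValueError("cannot place a non-positive number of lipids on a grid")
    nx = int(np.floor(np.sqrt(n)))
    while n % nx:
        nx -= 1
    return nx, n // nx


def _lipid_axis_offsets() -> np.ndarray:
    """Bead offsets (terminal_tail, tail, head) along the outward lipid axis."""
    return np.array([0.0, BEAD_SPACING, 2 * BEAD_SPACING])


def _half_thickness(spec: GeometrySpec) -> float:
    """Distance from bilayer midplane to the head plane."""
    return spec.leaflet_separation / 2.0 + 2 * BEAD_SPACING


def _assemble(parts: list[tuple[np.ndarray, int, int]],
              box: np.ndarray, periodic: np.ndarray) -> ParticleConfiguration:
    pos = np.array([p for p, _, _ in parts], dtype=float)
    roles = np.array([r for _, r, _ in parts], dtype=int)
    lids = np.array([l for _, _, l in parts], dtype=int)
    return ParticleConfiguration(pos, roles, lids, box, periodic).wrapped()


def _fill_slab_water(rng: np.random.Generator, spec: GeometrySpec,
                     box: np.ndarray, z_lo: float, z_hi: float) -> np.ndarray:
    """Uniform random water in the full-lateral slab z in [z_lo, z_hi]."""
    vol = box[0] * box[1] * max(z_hi - z_lo, 0.0)
    n = int(round(spec.water_density * vol))
    if n == 0:
        return np.empty((0, 3))
    xy = rng.uniform(0.0, 1.0, size=(n, 2)) * box[:2]
    z = rng.uniform(z_lo, z_hi, size=(n, 1))
    return np.hstack([xy, z])


def build_flat_bilayer(spec: GeometrySpec) -> ParticleConfiguration:
    """Flat bilayer centred at the box z mid-plane, heads pointing outward.

    Lipids are placed on two rectangular leaflet grids; water fills the two
    solvent slabs above and below the head planes at ``spec.water_density``.
    """
    if spec.stripe:
        raise ValueError("spec.stripe must be False for a flat bilayer")
    if spec.pore_radius != 0:
        raise ValueError("pore_radius must be 0 for a flat bilayer")
    rng = np.random.default_rng(spec.seed)
    n_half = spec.n_lipids // 2
    nx, ny = _grid_factorization(n_half)
    s = np.sqrt(spec.area_per_lipid)
    box = np.array([nx * s, ny * s, 2 * _half_thickness(spec) + 2 * spec.water_pad])
    zc = box[2] / 2.0
    offsets = _lipid_axis_offsets()  # (tt, t, h) outward

    parts: list[tuple[np.ndarray, int, int]] = []
    lid = 0
    for leaflet, sign in ((0, 1.0), (1, -1.0)):
        base_z = zc + sign * spec.leaflet_separation / 2.0
        for ix in range(nx):
            for iy in range(ny):
                x = (ix + 0.5) * s + rng.uniform(-spec.jitter, spec.jitter)
                y = (iy + 0.5) * s + rng.uniform(-spec.jitter, spec.jitter)
                z = base_z + sign * offsets
                for role, zz in ((TERMINAL_TAIL, z[0]), (TAIL, z[1]), (HEAD, z[2])):
                    parts.append((np.array([x, y, zz]), role, lid))
                lid += 1

    head_hi = zc + _half_thickness(spec)
    head_lo = zc - _half_thickness(spec)
    for w in _fill_slab_water(rng, spec, box, head_hi + 0.1, box[2]):
        parts.append((w, WATER, -1))
    for w in _fill_slab_water(rng, spec, box, 0.0, head_lo - 0.1):
        parts.append((w, WATER, -1))

    return _assemble(parts, box, np.ones(3, dtype=bool))


def build_pore_bilayer(spec: GeometrySpec) -> ParticleConfiguration:
    """Bilayer with a cylindrical pore and a transmembrane water column.

    Lipids that would fall inside the pore footprint are relocated onto the
    pore rim, reoriented radially so their heads line the pore wall (a
    toroidal-cap stand-in); lipid and role counts are conserved relative to
    the flat bilayer of the same spec.  Water fills both solvent slabs and
    the cylindrical channel so that, for ``pore_radius >= 0.5`` nm at the
    default water density, every 0.25 nm z-slice through the core is wet.
    """
    if spec.pore_radius <= 0:
        raise ValueError("pore_radius must be > 0 for a pore bilayer")
    flat = build_flat_bilayer(replace(spec, pore_radius=0.0))
    box = flat.box
    if spec.pore_radius > min(box[0], box[1]) / 2.0:
        raise ValueError("pore_radius exceeds half the smallest lateral box edge")
    rng = np.random.default_rng(spec.seed + 1)
    zc = box[2] / 2.0
    center = box[:2] / 2.0

    pos = flat.positions.copy()
    # Tail clearance: a lipid is "inside the pore" if its grid site is closer
    # than pore_radius + clearance, so relocated-rim tails keep the contract
    # that no tail lies within pore_radius of the axis.
    clearance = spec.jitter + 1e-6
    inside_lids = []
    for lid in range(flat.n_lipids):
        sel = flat.lipid_ids == lid
        rho = np.linalg.norm(pos[sel][:, :2] - center, axis=1)
        if rho.min() < spec.pore_radius + clearance:
            inside_lids.append(lid)

    # Relocate the displaced lipids onto the rim: heads line the pore wall,
    # tails tucked just behind it so the closest tail distance equals the
    # requested radius (up to a small clearance); alternating z offsets and a
    # head-to-leaflet tilt sketch the toroidal cap.
    n_rim = len(inside_lids)
    for k, lid in enumerate(inside_lids):
        theta = 2 * np.pi * k / max(n_rim, 1)
        z_off = 0.45 * np.sin(np.pi * (k % 4) / 2.0 - np.pi / 4.0)
        tilt = 1.0 if k % 2 else -1.0
        u = np.array([np.cos(theta), np.sin(theta)])
        sel = np.where(flat.lipid_ids == lid)[0]
        # (radius, extra z) per role: head at the wall, first tail just
        # outside pore_radius, terminal tail behind it
        place = {HEAD: (spec.pore_radius, 0.4 * tilt),
                 TAIL: (spec.pore_radius + 0.08, 0.0),
                 TERMINAL_TAIL: (spec.pore_radius + 0.5, -0.25 * tilt)}
        for idx in sel:
            r, dz = place[flat.roles[idx]]
            pos[idx, :2] = center + r * u
            pos[idx, 2] = zc + z_off + dz

    parts = [(pos[i], flat.roles[i], flat.lipid_ids[i]) for i in range(flat.n_particles)]

    # Water column: per 0.25 nm slice across the membrane core, place
    # round(density * slice volume) waters uniformly in a channel of radius
    # 0.7 * pore_radius (kept off the rim heads).  Occupancy emerges from the
    # density, not from forced placement.
    h = _half_thickness(spec)
    r_w = 0.7 * spec.pore_radius
    slice_w = 0.25
    n_slices = int(np.ceil(2 * h / slice_w))
    for k in range(n_slices):
        z_lo = zc - h + k * slice_w
        n_w = int(round(spec.water_density * np.pi * r_w ** 2 * slice_w))
        for _ in range(n_w):
            rho = r_w * np.sqrt(rng.uniform())
            ang = rng.uniform(0, 2 * np.pi)
            z = rng.uniform(z_lo, min(z_lo + slice_w, zc + h))
            parts.append((np.array([center[0] + rho * np.cos(ang),
                                    center[1] + rho * np.sin(ang), z]), WATER, -1))

    return _assemble(parts, box, np.ones(3, dtype=bool))


def build_stripe(spec: GeometrySpec) -> ParticleConfiguration:
    """Lipid stripe: a bilayer ribbon, periodic along y, with two rims.

    The membrane normal is x (box edge ``spec.normal_edge``, default 8.5 nm),
    the rim axis is y (continuous through the periodic boundary), and the
    ribbon has a finite width along z terminated by two hemicylindrical
    head-capped rims.  The rim-rim distance through the z boundary is
    ``spec.rim_gap`` and must be at least 2 nm so the two edges do not
    interact.  Lipid count equals that of the flat bilayer of the same spec.
    """
    if not spec.stripe:
        raise ValueError("spec.stripe must be True for a stripe")
    if spec.rim_gap < 2.0:
        raise ValueError("rim-rim gap must be at least 2 nm")
    rng = np.random.default_rng(spec.seed)
    n_half = spec.n_lipids // 2
    s = np.sqrt(spec.area_per_lipid)

    if spec.rim_length is None:
        ny, nz = _grid_factorization(n_half)
    else:
        ny = max(1, int(round(spec.rim_length / s)))
        while n_half % ny:
            ny -= 1
        nz = n_half // ny
    L_y = ny * s
    W_z = nz * s
    half_t = _half_thickness(spec)
    box = np.array([spec.normal_edge, L_y, W_z + 2 * half_t + spec.rim_gap])
    xc = box[0] / 2.0
    z0 = (box[2] - W_z) / 2.0  # ribbon body start in z

    offsets = _lipid_axis_offsets()
    parts: list[tuple[np.ndarray, int, int]] = []
    lid = 0
    # Edge rows (iz == 0 and iz == nz-1) are placed on hemicylindrical caps.
    for leaflet, sign in ((0, 1.0), (1, -1.0)):
        base_x = xc + sign * spec.leaflet_separation / 2.0
        for iz in range(nz):
            for iy in range(ny):
                y = (iy + 0.5) * s + rng.uniform(-spec.jitter, spec.jitter)
                if iz == 0 or iz == nz - 1:
                    edge_z = z0 if iz == 0 else z0 + W_z
                    out = -1.0 if iz == 0 else 1.0
                    # quarter-circle angle per leaflet: 0 = in-plane (along z),
                    # pi/2 would be membrane-normal; stagger by leaflet for a
                    # hemicylindrical cap around the edge line.
                    ang = np.deg2rad(30.0 if leaflet == 0 else -30.0)
                    axis = np.array([sign * np.sin(ang), 0.0, out * np.cos(ang)])
                    tip = np.array([xc + sign * spec.leaflet_separation / 2.0, y, edge_z])
                    for role, off in ((TERMINAL_TAIL, offsets[0]),
                                      (TAIL, offsets[1]), (HEAD, offsets[2])):
                        parts.append((tip + off * axis, role, lid))
                else:
                    z = z0 + (iz + 0.5) * s + rng.uniform(-spec.jitter, spec.jitter)
                    x = base_x + sign * offsets
                    for role, xx in ((TERMINAL_TAIL, x[0]), (TAIL, x[1]), (HEAD, x[2])):
                        parts.append((np.array([xx, y, z]), role, lid))
                lid += 1

    # Solvent fill outside the ribbon bounding slab (|x - xc| > half_t + 0.1
    # or z outside the capped body).
    vol_box = float(np.prod(box))
    body_x = 2 * (half_t + 0.1)
    body_z = W_z + 2 * half_t
    vol_body = body_x * box[1] * min(body_z, box[2])
    n_w = int(round(spec.water_density * max(vol_box - vol_body, 0.0)))
    placed = 0
    while placed < n_w:
        p = rng.uniform(0.0, 1.0, size=3) * box
        in_x = abs(p[0] - xc) < half_t + 0.1
        in_z = (z0 - half_t) < p[2] < (z0 + W_z + half_t)
        if in_x and in_z:
            continue
        parts.append((p, WATER, -1))
        placed += 1

    periodic = np.array([True, True, True])
    return _assemble(parts, box, periodic)


def recenter_lipids(config: ParticleConfiguration,
                    axes: tuple[int, ...] = (0, 1)) -> ParticleConfiguration:
    """Translate the system so the lipid centre of geometry sits at the box
    centre along the given axes (default: the membrane plane xy).

    The pore-centre convention of the Full-Path CV is the geometric box
    centre; apply this helper first if a trajectory has drifted.
    """
    out = config.copy()
    cog = out.positions[out.lipid_mask].mean(axis=0)
    for ax in axes:
        out.positions[:, ax] += out.box[ax] / 2.0 - cog[ax]
    return out.wrapped()
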