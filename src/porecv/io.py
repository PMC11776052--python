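"""Coordinate and time-series I/O.

GRO files (nm, single frame) are read and written through MDAnalysis; the
particle role is encoded in the atom name (H = head, T = tail, TT = terminal
tail, W = water) and lipid membership in the residue numbering (one residue
per lipid, resname LIP; water residues SOL).  Multi-frame trajectories use an
extended XYZ dialect whose comment line declares the box, periodicity and
unit, because plain XYZ carries neither a box nor units.  CV time series use
the COLVAR-style whitespace-separated text format with a ``#! FIELDS`` header.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .membranes import (HEAD, ROLE_NAMES, TAIL, TERMINAL_TAIL, WATER,
                        ParticleConfiguration)

__all__ = [
    "ATOM_NAMES",
    "read_coordinates",
    "write_coordinates",
    "read_gro",
    "write_gro",
    "read_xyz",
    "write_xyz",
    "read_series",
    "write_series",
]

ATOM_NAMES = {HEAD: "H", TAIL: "T", TERMINAL_TAIL: "TT", WATER: "W"}
_NAME_TO_ROLE = {"H": HEAD, "T": TAIL, "TT": TERMINAL_TAIL, "W": WATER,
                 "OW": WATER}


def _role_from_name(name: str) -> int:
    key = name.strip().upper()
    if key not in _NAME_TO_ROLE:
        raise ValueError(
            f"unknown atom name {name!r}; known names: "
            + ", ".join(sorted(_NAME_TO_ROLE)))
    return _NAME_TO_ROLE[key]


# --------------------------------------------------------------------------
# GRO (single frame, via MDAnalysis)
# --------------------------------------------------------------------------

def write_gro(path: Union[str, Path], config: ParticleConfiguration) -> None:
    """Write a configuration as a GRO file (nm, box footer)."""
    import MDAnalysis as mda

    n = config.n_particles
    n_res = config.n_lipids + int(np.sum(config.roles == WATER))
    resindex = np.empty(n, dtype=int)
    resindex[config.lipid_mask] = config.lipid_ids[config.lipid_mask]
    water_idx = np.where(config.roles == WATER)[0]
    resindex[water_idx] = config.n_lipids + np.arange(len(water_idx))
    resnames = np.array(["LIP"] * config.n_lipids + ["SOL"] * len(water_idx))

    u = mda.Universe.empty(n, n_residues=max(n_res, 1),
                           atom_resindex=resindex,
                           residue_segindex=np.zeros(max(n_res, 1), dtype=int),
                           trajectory=True)
    u.add_TopologyAttr("names", [ATOM_NAMES[r] for r in config.roles])
    u.add_TopologyAttr("resnames", resnames if n_res else ["SOL"])
    u.add_TopologyAttr("resids", np.arange(1, max(n_res, 1) + 1))
    u.atoms.positions = config.positions * 10.0  # nm -> Angstrom
    u.dimensions = [config.box[0] * 10, config.box[1] * 10, config.box[2] * 10,
                    90, 90, 90]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def read_gro(path: Union[str, Path]) -> ParticleConfiguration:
    """Read a GRO file into a ParticleConfiguration (positions in nm).

    Roles are inferred from atom names; lipid ids from the residue numbering
    of LIP residues.  A missing or zero box line is an error.
    """
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:
        raise ValueError(f"malformed GRO file {path}: {exc}") from exc
    if u.dimensions is None or np.any(u.dimensions[:3] <= 0):
        raise ValueError(f"GRO file {path} has no valid box line")
    roles = np.array([_role_from_name(nm) for nm in u.atoms.names])
    lipid_ids = np.full(len(roles), -1, dtype=int)
    lip_res = {}
    for i, atom in enumerate(u.atoms):
        if roles[i] != WATER:
            rid = atom.resid
            lip_res.setdefault(rid, len(lip_res))
            lipid_ids[i] = lip_res[rid]
    return ParticleConfiguration(
        positions=u.atoms.positions / 10.0,
        roles=roles, lipid_ids=lipid_ids,
        box=np.asarray(u.dimensions[:3], dtype=float) / 10.0)


# --------------------------------------------------------------------------
# extended XYZ (multi-frame; box + unit on the comment line)
# --------------------------------------------------------------------------

def write_xyz(path: Union[str, Path],
              frames: Union[ParticleConfiguration, Sequence[ParticleConfiguration]],
              unit: str = "nm") -> None:
    """Write one or more frames as extended XYZ.

    The comment line is ``box=<Lx> <Ly> <Lz> unit=<nm|angstrom>
    periodic=<xyz flags>`` so the file round-trips losslessly.
    """
    if isinstance(frames, ParticleConfiguration):
        frames = [frames]
    scale = {"nm": 1.0, "angstrom": 10.0}[unit]
    with open(path, "w") as fh:
        for cfg in frames:
            fh.write(f"{cfg.n_particles}\n")
            bx = cfg.box * scale
            per = "".join("1" if p else "0" for p in cfg.periodic)
            fh.write(f"box={bx[0]:.6f} {bx[1]:.6f} {bx[2]:.6f} "
                     f"unit={unit} periodic={per}\n")
            for name_code, pos in zip(cfg.roles, cfg.positions * scale):
                fh.write(f"{ATOM_NAMES[name_code]:4s} "
                         f"{pos[0]:12.6f} {pos[1]:12.6f} {pos[2]:12.6f}\n")


def _parse_xyz_comment(line: str):
    box = None
    unit = "nm"
    periodic = np.ones(3, dtype=bool)
    for token in line.replace(",", " ").split():
        if token.startswith("box="):
            vals = token[4:].split()
        elif token.startswith("unit="):
            unit = token[5:]
        elif token.startswith("periodic="):
            periodic = np.array([c == "1" for c in token[9:]], dtype=bool)
    # box may span three whitespace-separated tokens after box=
    if "box=" in line:
        rest = line.split("box=", 1)[1].split()
        vals = []
        for tok in rest:
            if "=" in tok:
                break
            vals.append(float(tok))
        box = np.array(vals[:3], dtype=float)
    return box, unit, periodic


def read_xyz(path: Union[str, Path]) -> List[ParticleConfiguration]:
    """Read an extended XYZ trajectory (see :func:`write_xyz`).

    The declared unit on the comment line is honoured; lipid ids are
    reconstructed by grouping consecutive head/tail/terminal triplets.
    """
    frames: List[ParticleConfiguration] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(
                f"{path}:{i + 1}: expected atom count, got {lines[i]!r}") from exc
        box, unit, periodic = _parse_xyz_comment(lines[i + 1])
        if box is None:
            raise ValueError(f"{path}:{i + 2}: comment line lacks box=...")
        scale = {"nm": 1.0, "angstrom": 0.1}[unit]
        roles = np.empty(n, dtype=int)
        pos = np.empty((n, 3))
        for k in range(n):
            parts = lines[i + 2 + k].split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{i + 3 + k}: malformed atom line")
            roles[k] = _role_from_name(parts[0])
            pos[k] = [float(v) for v in parts[1:4]]
        lipid_ids = _infer_lipid_ids(roles)
        frames.append(ParticleConfiguration(
            positions=pos * scale, roles=roles, lipid_ids=lipid_ids,
            box=box * scale, periodic=periodic))
        i += 2 + n
        frame_no += 1
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return frames


def _infer_lipid_ids(roles: np.ndarray) -> np.ndarray:
    """Group consecutive non-water atoms into lipids, starting a new lipid at
    each terminal-tail...head boundary (builders emit terminal, tail, head
    or head, tail, terminal runs; any consistent consecutive grouping where
    a head starts/ends a lipid works)."""
    lipid_ids = np.full(len(roles), -1, dtype=int)
    lid = -1
    prev_role: Optional[int] = None
    for i, r in enumerate(roles):
        if r == WATER:
            prev_role = None
            continue
        if prev_role is None or (r == TERMINAL_TAIL and prev_role in (HEAD, TERMINAL_TAIL)) \
                or (r == HEAD and prev_role in (HEAD, TERMINAL_TAIL)):
            lid += 1
        lipid_ids[i] = lid
        prev_role = r
    return lipid_ids


def read_coordinates(path: Union[str, Path], fmt: Optional[str] = None):
    """Read GRO (single configuration) or XYZ (list of frames); the format is
    inferred from the suffix unless given."""
    fmt = (fmt or Path(path).suffix.lstrip(".")).lower()
    if fmt == "gro":
        return read_gro(path)
    if fmt == "xyz":
        return read_xyz(path)
    raise ValueError(f"unsupported coordinate format {fmt!r} (use gro or xyz)")


def write_coordinates(path: Union[str, Path], frames,
                      fmt: Optional[str] = None) -> None:
    fmt = (fmt or Path(path).suffix.lstrip(".")).lower()
    if fmt == "gro":
        if not isinstance(frames, ParticleConfiguration):
            raise ValueError("GRO output holds a single configuration")
        write_gro(path, frames)
    elif fmt == "xyz":
        write_xyz(path, frames)
    else:
        raise ValueError(f"unsupported coordinate format {fmt!r} (use gro or xyz)")


# --------------------------------------------------------------------------
# COLVAR-style series
# --------------------------------------------------------------------------

def write_series(path: Union[str, Path], df: pd.DataFrame,
                 precision: int = 8) -> None:
    """Write a time series as COLVAR-style text: ``#! FIELDS <names>`` header
    followed by fixed-precision whitespace-separated columns."""
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(df.columns) + "\n")
        np.savetxt(fh, df.to_numpy(), fmt=f"%.{precision}g")


def read_series(path: Union[str, Path],
                columns: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Read a COLVAR-style series into a DataFrame.

    Comment lines (#) are skipped; the ``#! FIELDS`` header is mandatory and
    names the columns.  Requesting an absent column raises an error naming
    the available ones; ragged rows are an error with their line number.
    """
    names = None
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#! FIELDS"):
                names = s.split()[2:]
                continue
            if s.startswith("#"):
                continue
            if names is None:
                raise ValueError(f"{path}: missing '#! FIELDS' header")
            vals = s.split()
            if len(vals) != len(names):
                raise ValueError(
                    f"{path}:{ln}: expected {len(names)} columns, got {len(vals)}")
            rows.append([float(v) for v in vals])
    if names is None:
        raise ValueError(f"{path}: missing '#! FIELDS' header")
    df = pd.DataFrame(rows, columns=names)
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise KeyError(
                f"column(s) {missing} not in series; available: {list(df.columns)}")
        df = df[list(columns)]
    return df
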