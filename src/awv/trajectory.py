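"""Trajectory container, extended-XYZ I/O, and kinematic preprocessing.

The spectroscopy pipeline needs, per frame, atomic positions ξ(t),
velocities v(t) and accelerations a(t).  MD engines commonly dump only
positions (sometimes velocities); the missing derivatives are obtained
here by five-point central finite differences, which are exact for
polynomials up to degree four and carry an O(dt⁴) truncation error.

For gas-phase systems the overall tumbling of the molecule contaminates
the velocity field with rigid-rotation components that do not belong to
the vibrational spectrum; :func:`remove_global_rotation` produces the
rotation-free trajectory ξ_vib(t) = R(t)·ξ(t) with R(t) the mass-weighted
quaternion superposition onto a reference frame.
"""

from __future__ import annotations

import re
import shlex
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .units import mass_of

__all__ = [
    "Trajectory",
    "Topology",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "five_point_derivative",
    "finite_difference_derivatives",
    "DerivativeFrames",
    "remove_global_rotation",
    "wrap_molecules",
]

#: Five-point central first-derivative stencil, divided by 12·dt at use site.
_STENCIL = np.array([1.0, -8.0, 0.0, 8.0, -1.0])


@dataclass
class Trajectory:
    """Time-ordered atomic coordinates with element/mass metadata.

    Parameters
    ----------
    positions
        Array ``(n_frames, n_atoms, 3)`` in Å.
    dt
        Time step between consecutive frames, fs.
    elements
        Per-atom element symbols, length ``n_atoms``.
    masses
        Per-atom masses in amu; derived from ``elements`` if omitted.
    velocities
        Optional ``(n_frames, n_atoms, 3)`` in Å/fs, e.g. from the MD
        engine's restart dump.  When present they take precedence over
        differentiated positions.
    box
        Optional orthorhombic box edge lengths (3,) in Å.
    """

    positions: np.ndarray
    dt: float
    elements: Sequence[str]
    masses: np.ndarray | None = None
    velocities: np.ndarray | None = None
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_atoms, 3)")
        if not np.isfinite(self.positions).all():
            raise ValueError("positions contain non-finite values")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        self.elements = list(self.elements)
        if len(self.elements) != self.n_atoms:
            raise ValueError("elements length does not match atom count")
        if self.masses is None:
            self.masses = np.array([mass_of(e) for e in self.elements])
        else:
            self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (self.n_atoms,) or (self.masses <= 0).any():
            raise ValueError("masses must be positive, one per atom")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities shape must match positions")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if (self.box <= 0).any():
                raise ValueError("box lengths must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in fs, starting at 0."""
        return np.arange(self.n_frames) * self.dt


@dataclass
class Topology:
    """Partition of the atoms into molecules (disjoint index sets)."""

    molecules: list[np.ndarray]
    n_atoms: int = 0

    def __post_init__(self) -> None:
        self.molecules = [np.asarray(m, dtype=int) for m in self.molecules]
        flat = np.concatenate(self.molecules) if self.molecules else np.array([], int)
        if len(set(flat.tolist())) != flat.size:
            raise ValueError("molecule atom sets overlap")
        if self.n_atoms == 0:
            self.n_atoms = flat.size
        if sorted(flat.tolist()) != list(range(self.n_atoms)):
            raise ValueError("molecules must cover atoms 0..n_atoms-1 exactly")

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)


# ---------------------------------------------------------------------------
# extended-XYZ I/O


def _parse_comment(line: str) -> dict[str, str]:
    """Parse an extended-XYZ comment line of key=value tokens.

    Quoted values (Lattice="...") are kept whole; bare tokens without '='
    are ignored, which also makes plain-XYZ comment lines acceptable.
    """
    out: dict[str, str] = {}
    try:
        tokens = shlex.split(line)
    except ValueError:
        return out
    for tok in tokens:
        if "=" in tok:
            k, v = tok.split("=", 1)
            out[k] = v
    return out


def _parse_properties(prop: str) -> list[tuple[str, str, int]]:
    parts = prop.split(":")
    if len(parts) % 3:
        raise ValueError(f"malformed Properties string: {prop!r}")
    return [
        (parts[i], parts[i + 1], int(parts[i + 2])) for i in range(0, len(parts), 3)
    ]


def read_xyz_trajectory(
    path: str | Path,
    dt: float,
    masses: np.ndarray | None = None,
) -> Trajectory:
    """Read a (extended-)XYZ trajectory file.

    Supports the ASE dialect header ``Lattice="..." Properties=...`` with
    per-atom columns ``species:S:1:pos:R:3`` and optionally ``vel:R:3``
    (either as a ``vel`` or ``velocities`` field).  Plain XYZ files are
    accepted; ``dt`` always comes from the caller.
    """
    lines = Path(path).read_text().splitlines()
    frames_pos: list[np.ndarray] = []
    frames_vel: list[np.ndarray] = []
    elements: list[str] | None = None
    box = None
    i = 0
    nline = len(lines)
    while i < nline:
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"expected atom count at line {i + 1}") from exc
        if i + 1 + nat >= nline + 1:
            raise ValueError("truncated frame at end of file")
        header = _parse_comment(lines[i + 1])
        if "Lattice" in header and box is None:
            cell = np.fromstring(header["Lattice"], sep=" ").reshape(3, 3)
            off = cell - np.diag(np.diag(cell))
            if np.abs(off).max() > 1e-10:
                raise ValueError("only orthorhombic (diagonal) lattices supported")
            box = np.diag(cell).copy()
        vel_col = None
        if "Properties" in header:
            col = 0
            for name, _kind, ncol in _parse_properties(header["Properties"]):
                if name in ("vel", "velocities", "velo"):
                    vel_col = col
                col += ncol
        body = lines[i + 2 : i + 2 + nat]
        if len(body) != nat:
            raise ValueError(f"truncated frame starting at line {i + 1}")
        syms = [ln.split()[0] for ln in body]
        data = np.array([[float(x) for x in ln.split()[1:]] for ln in body])
        if elements is None:
            elements = syms
        elif syms != elements or nat != len(elements):
            raise ValueError(
                f"inconsistent atom count/order in frame {len(frames_pos)}"
            )
        frames_pos.append(data[:, 0:3])
        if vel_col is not None:
            # vel_col counts from the species column; numeric data starts after it
            frames_vel.append(data[:, vel_col - 1 : vel_col + 2])
        elif data.shape[1] >= 6 and "Properties" not in header:
            frames_vel.append(data[:, 3:6])  # bare 7-column XYZ convention
        i += 2 + nat

    if elements is None:
        raise ValueError(f"no frames found in {path}")
    if len(frames_pos) < 5:
        raise ValueError(
            f"{len(frames_pos)} frames read; at least 5 are required for "
            "five-point differentiation"
        )
    vel = np.array(frames_vel) if len(frames_vel) == len(frames_pos) else None
    return Trajectory(
        positions=np.array(frames_pos),
        dt=dt,
        elements=elements,
        masses=masses,
        velocities=vel,
        box=box,
    )


def write_xyz_trajectory(path: str | Path, traj: Trajectory) -> None:
    """Write an extended-XYZ file (ASE dialect) with full float precision."""
    props = "species:S:1:pos:R:3"
    if traj.velocities is not None:
        props += ":vel:R:3"
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            header = f"Properties={props} Time={f * traj.dt:.6f}"
            if traj.box is not None:
                b = traj.box
                header = (
                    f'Lattice="{b[0]:.10g} 0.0 0.0 0.0 {b[1]:.10g} 0.0 '
                    f'0.0 0.0 {b[2]:.10g}" ' + header
                )
            fh.write(header + "\n")
            for a in range(traj.n_atoms):
                row = f"{traj.elements[a]:<3s}" + "".join(
                    f" {x:.12e}" for x in traj.positions[f, a]
                )
                if traj.velocities is not None:
                    row += "".join(f" {x:.12e}" for x in traj.velocities[f, a])
                fh.write(row + "\n")


# ---------------------------------------------------------------------------
# finite differences


def five_point_derivative(y: np.ndarray, dt: float) -> np.ndarray:
    """First time derivative by the five-point central stencil.

    ``y`` has time on axis 0; the result drops two frames at each end,
    shape ``(n-4, ...)``.  Exact for polynomials of degree ≤ 4.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 5:
        raise ValueError(f"need at least 5 frames, got {n}")
    if not np.isfinite(y).all():
        raise ValueError("non-finite values in series")
    return (
        y[:-4] - 8.0 * y[1:-3] + 8.0 * y[3:-1] - y[4:]
    ) / (12.0 * dt)


class DerivativeFrames(NamedTuple):
    """Velocities and accelerations on their common frame support."""

    velocities: np.ndarray  # (n_usable, n_atoms, 3) Å/fs
    accelerations: np.ndarray  # (n_usable, n_atoms, 3) Å/fs²
    frames: np.ndarray  # indices into the source trajectory


def finite_difference_derivatives(traj: Trajectory) -> DerivativeFrames:
    """Velocities and accelerations for a trajectory.

    File-provided velocities take precedence (accelerations are then their
    five-point derivative, keeping a consistent with v); otherwise
    velocities are differentiated from positions first.  Two frames are
    dropped at each end per differentiation pass.
    """
    if traj.velocities is not None:
        vel = traj.velocities
        acc = five_point_derivative(vel, traj.dt)
        frames = np.arange(2, traj.n_frames - 2)
        return DerivativeFrames(vel[2:-2], acc, frames)
    if traj.n_frames < 9:
        raise ValueError(
            "at least 9 frames are needed to differentiate positions twice; "
            f"got {traj.n_frames}"
        )
    vel_full = five_point_derivative(traj.positions, traj.dt)  # frames 2..n-3
    acc = five_point_derivative(vel_full, traj.dt)  # frames 4..n-5
    frames = np.arange(4, traj.n_frames - 4)
    return DerivativeFrames(vel_full[2:-2], acc, frames)


# ---------------------------------------------------------------------------
# global-rotation removal and PBC unwrapping


def remove_global_rotation(traj: Trajectory, reference_frame: int = 0) -> Trajectory:
    """Project out overall tumbling: ξ_vib(t) = R(t)·(ξ(t) − com) + com_ref.

    Each frame is superposed onto ``reference_frame`` by the mass-weighted
    quaternion fit.  Velocities, if present, are discarded (they would
    need the same time-dependent rotation plus its derivative; downstream
    differentiation of the rotated positions is the consistent route).
    """
    from .matching import fit_rotations_batch  # deferred: avoids import cycle

    ref = traj.positions[reference_frame]
    masses = traj.masses
    com_ref = masses @ ref / masses.sum()
    rots = fit_rotations_batch(traj.positions, ref, masses)
    com = np.einsum("a,fax->fx", masses, traj.positions) / masses.sum()
    centered = traj.positions - com[:, None, :]
    newpos = np.einsum("fxy,fay->fax", rots, centered) + com_ref
    return replace(traj, positions=newpos, velocities=None)


def wrap_molecules(traj: Trajectory, topo: Topology) -> Trajectory:
    """Make each molecule whole under periodic boundaries.

    Every atom is shifted by whole box vectors to its minimum image about
    the molecule's first atom.  Fails when a wrapped molecule spans half
    the box (whole-molecule reconstruction then being ambiguous).
    """
    if traj.box is None:
        raise ValueError("wrap_molecules requires a periodic box")
    box = traj.box
    pos = traj.positions.copy()
    for mol in topo.molecules:
        anchor = pos[:, mol[0] : mol[0] + 1, :]
        delta = pos[:, mol, :] - anchor
        pos[:, mol, :] -= np.rint(delta / box) * box
        extent = pos[:, mol, :].max(axis=1) - pos[:, mol, :].min(axis=1)
        if (extent >= 0.5 * box).any():
            raise ValueError(
                f"molecule with atoms {mol.tolist()} spans ≥ half the box; "
                "cannot be unwrapped unambiguously"
            )
    return replace(traj, positions=pos)
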