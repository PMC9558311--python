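"""Time evolution of APT/AAT tensors along a trajectory.

The electric and magnetic dipole derivatives μ̇ = P·v and ṁ = M·a need
P(t) and M(t) at every usable frame.  Because these tensors vary one to
two orders of magnitude more slowly than the atomic velocities, they are
interpolated from a library of reference structures:

    P_i(t) = Σ_j w_j(t) · R_j(t) · P_i^ref(j) · R_j(t)ᵀ

(and identically for the local-gauge AAT blocks), with w_j(t) the
Gaussian metric weights and R_j(t) the mass-weighted quaternion rotation
superposing reference j onto the instantaneous geometry.  The
divide-and-conquer variant applies the same formula fragment by
fragment, with fragment-local metrics and rotations, turning the
exponential growth of the required reference set with molecular
flexibility into an almost linear one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .matching import (
    MetricSpec,
    _wrap_angle,
    compute_weights,
    evaluate_metric_coordinates,
    fit_rotations_batch,
    resolve_sigmas,
)
from .reference import ReferenceStructure, gauge_transform_aat
from .trajectory import Topology, Trajectory

__all__ = [
    "FragmentDefinition",
    "TensorSeries",
    "DerivativeSeries",
    "evolve_tensors_global",
    "evolve_tensors_fragments",
    "weighted_derivatives",
]


@dataclass
class FragmentDefinition:
    """A molecular unit evolved with its own references and metric.

    ``atoms`` are molecule-local indices; ``ref_atoms`` maps each of them
    to the corresponding atom of the reference geometries (identity by
    default, for references that model exactly the fragment).  Fragments
    with fewer than 3 atoms cannot define a rotation and must set
    ``allow_small=True`` to be evolved with the identity rotation.
    """

    name: str
    atoms: Sequence[int]
    references: list[ReferenceStructure]
    metric_spec: MetricSpec
    ref_atoms: Sequence[int] | None = None
    allow_small: bool = False

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, int)
        if self.ref_atoms is None:
            self.ref_atoms = np.arange(len(self.atoms))
        else:
            self.ref_atoms = np.asarray(self.ref_atoms, int)
        if len(self.ref_atoms) != len(self.atoms):
            raise ValueError(f"fragment {self.name!r}: ref_atoms/atoms length mismatch")
        if len(self.atoms) < 3 and not self.allow_small:
            raise ValueError(
                f"fragment {self.name!r} has {len(self.atoms)} atoms; a rotation "
                "fit needs ≥ 3 — set allow_small=True to use the identity rotation"
            )
        if not self.references:
            raise ValueError(f"fragment {self.name!r} has no reference structures")


@dataclass
class TensorSeries:
    """Per-frame evolved tensors for every atom of the system.

    ``aat_local`` blocks are still in the distributed-origin gauge
    (rotated into the lab orientation); the transfer to a common origin
    happens in :func:`weighted_derivatives` using the instantaneous
    positions, as the gauge correction is configuration-dependent.
    """

    apt: np.ndarray  # (n_frames, n_atoms, 3, 3)
    aat_local: np.ndarray  # (n_frames, n_atoms, 3, 3)
    frames: np.ndarray  # indices into the source trajectory
    positions: np.ndarray  # (n_frames, n_atoms, 3) snapshot, Å
    dt: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.apt).all() and np.isfinite(self.aat_local).all()):
            raise ValueError("non-finite evolved tensors")


@dataclass
class DerivativeSeries:
    """Per-molecule dipole/magnetic derivative fluctuations.

    ``mu_dot`` and ``m_dot`` have shape ``(n_frames, n_molecules, 3)``;
    the time mean of each component has already been subtracted, matching
    the fluctuation convention of the correlation formalism.
    """

    mu_dot: np.ndarray
    m_dot: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        if self.mu_dot.shape != self.m_dot.shape:
            raise ValueError("mu_dot and m_dot must have the same shape")
        if not (np.isfinite(self.mu_dot).all() and np.isfinite(self.m_dot).all()):
            raise ValueError("non-finite derivative series")

    @property
    def n_molecules(self) -> int:
        return self.mu_dot.shape[1]


def _metric_distances(
    coords: np.ndarray, refs: Sequence[ReferenceStructure], spec: MetricSpec,
    ref_atoms: np.ndarray,
) -> np.ndarray:
    """d_j^x for every frame and reference: shape (n_frames, n_refs, n_fam)."""
    frame_vals = evaluate_metric_coordinates(coords, spec)
    out = np.empty((coords.shape[0], len(refs), len(spec.families)))
    for j, ref in enumerate(refs):
        stored = ref.metric_values
        have_all = stored and all(f.name in stored for f in spec.families)
        rv = (
            {k: np.asarray(v, float) for k, v in stored.items()}
            if have_all
            else evaluate_metric_coordinates(ref.geometry[ref_atoms], spec)
        )
        for x, fam in enumerate(spec.families):
            delta = frame_vals[fam.name] - rv[fam.name]
            if fam.is_angular:
                delta = _wrap_angle(delta)
            out[:, j, x] = np.sqrt(np.mean(delta**2, axis=-1))
    return out


def _evolve_block(
    coords: np.ndarray,  # (F, k, 3) fragment coordinates per frame
    masses: np.ndarray,  # (k,)
    refs: Sequence[ReferenceStructure],
    spec: MetricSpec,
    ref_atoms: np.ndarray,
    stride: int,
    fit_rotation: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Evolved (apt, aat_local) blocks for one fragment, (F, k, 3, 3) each."""
    F, k = coords.shape[:2]
    spec = resolve_sigmas(spec, [r.geometry[ref_atoms] for r in refs]) if any(
        f.sigma is None for f in spec.families
    ) else spec
    eval_idx = np.arange(0, F, stride)
    d = _metric_distances(coords[eval_idx], refs, spec, ref_atoms)
    w_eval = np.stack([compute_weights(dj, spec) for dj in d])  # (Fe, J)
    weights = np.repeat(w_eval, stride, axis=0)[:F]
    apt = np.zeros((F, k, 3, 3))
    aat = np.zeros((F, k, 3, 3))
    for j, ref in enumerate(refs):
        wj = weights[:, j]
        if wj.max() < 1e-14:
            continue
        if fit_rotation:
            # fit maps frame→reference; the lab-frame rotation is its inverse
            R = fit_rotations_batch(
                coords, ref.geometry[ref_atoms], masses
            ).transpose(0, 2, 1)
        else:
            R = np.broadcast_to(np.eye(3), (F, 3, 3))
        P = ref.apt[ref_atoms]
        M = ref.aat_local[ref_atoms]
        apt += np.einsum("f,fab,ibc,fdc->fiad", wj, R, P, R, optimize=True)
        aat += np.einsum("f,fab,ibc,fdc->fiad", wj, R, M, R, optimize=True)
    return apt, aat


def evolve_tensors_global(
    traj: Trajectory,
    refs: Sequence[ReferenceStructure],
    metric_spec: MetricSpec,
    frames: np.ndarray | None = None,
    stride: int = 1,
) -> TensorSeries:
    """Evolve tensors treating the whole system as a single unit.

    ``frames`` selects the trajectory frames to evaluate (default: all);
    ``stride`` re-evaluates weights every ``stride`` frames with held
    values in between, exploiting the slow variation of P and M.
    """
    if refs[0].n_atoms != traj.n_atoms:
        raise ValueError(
            f"reference atom count {refs[0].n_atoms} != trajectory {traj.n_atoms}"
        )
    frames = np.arange(traj.n_frames) if frames is None else np.asarray(frames, int)
    coords = traj.positions[frames]
    ref_atoms = np.arange(traj.n_atoms)
    apt, aat = _evolve_block(
        coords, traj.masses, refs, metric_spec, ref_atoms, stride, fit_rotation=True
    )
    return TensorSeries(apt=apt, aat_local=aat, frames=frames, positions=coords,
                        dt=traj.dt)


def evolve_tensors_fragments(
    traj: Trajectory,
    topo: Topology,
    fragment_defs: Sequence[Sequence[FragmentDefinition]],
    frames: np.ndarray | None = None,
    stride: int = 1,
) -> TensorSeries:
    """Divide-and-conquer tensor evolution, fragment by fragment.

    ``fragment_defs[m]`` lists the fragments of molecule ``m`` (atom
    indices molecule-local, disjoint, covering the molecule).  Whole-
    system tensors are assembled by concatenating the per-fragment
    blocks.
    """
    if len(fragment_defs) != topo.n_molecules:
        raise ValueError("one fragment list per molecule is required")
    frames = np.arange(traj.n_frames) if frames is None else np.asarray(frames, int)
    coords = traj.positions[frames]
    F = len(frames)
    apt = np.zeros((F, traj.n_atoms, 3, 3))
    aat = np.zeros((F, traj.n_atoms, 3, 3))
    for m, (mol, frags) in enumerate(zip(topo.molecules, fragment_defs)):
        covered = np.concatenate([np.asarray(f.atoms, int) for f in frags])
        if len(set(covered.tolist())) != len(covered):
            raise ValueError(f"molecule {m}: fragment atom sets overlap")
        if sorted(covered.tolist()) != list(range(len(mol))):
            raise ValueError(
                f"molecule {m}: fragments do not cover its {len(mol)} atoms"
            )
        for frag in frags:
            atom_idx = mol[np.asarray(frag.atoms, int)]
            fa, fm = _evolve_block(
                coords[:, atom_idx],
                traj.masses[atom_idx],
                frag.references,
                frag.metric_spec,
                np.asarray(frag.ref_atoms, int),
                stride,
                fit_rotation=len(frag.atoms) >= 3,
            )
            apt[:, atom_idx] = fa
            aat[:, atom_idx] = fm
    return TensorSeries(apt=apt, aat_local=aat, frames=frames, positions=coords,
                        dt=traj.dt)


def weighted_derivatives(
    tensors: TensorSeries,
    velocities: np.ndarray,
    accelerations: np.ndarray,
    topo: Topology,
    gauge_origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> DerivativeSeries:
    """Form μ̇_m(t) = Σ_{i∈m} P_i(t)·v_i(t) and ṁ_m(t) = Σ_{i∈m} M_i^lab(t)·a_i(t).

    The local-gauge AAT blocks are transferred to the common lab origin
    with the instantaneous atomic positions before contraction.  The time
    mean of every component is subtracted (fluctuation convention).
    """
    if velocities.shape != tensors.positions.shape:
        raise ValueError("velocities do not match the tensor-series frames")
    if accelerations.shape != velocities.shape:
        raise ValueError("accelerations do not match velocities")
    aat_lab = gauge_transform_aat(
        tensors.aat_local, tensors.apt, tensors.positions, gauge_origin
    )
    F = tensors.apt.shape[0]
    M = topo.n_molecules
    mu_dot = np.empty((F, M, 3))
    m_dot = np.empty((F, M, 3))
    for m, mol in enumerate(topo.molecules):
        mu_dot[:, m] = np.einsum(
            "fiuw,fiw->fu", tensors.apt[:, mol], velocities[:, mol]
        )
        m_dot[:, m] = np.einsum(
            "fiuw,fiw->fu", aat_lab[:, mol], accelerations[:, mol]
        )
    mu_dot -= mu_dot.mean(axis=0)
    m_dot -= m_dot.mean(axis=0)
    return DerivativeSeries(mu_dot=mu_dot, m_dot=m_dot, dt=tensors.dt)
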