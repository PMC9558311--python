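"""Synthetic ground-truth systems: harmonic dynamics and a methyl rotor.

Two generators provide everything the package's validation needs without
any external data:

* :class:`HarmonicModel` — multi-mode normal-mode dynamics at classical
  equipartition with *constant* assigned APT/AAT tensors.  In this
  double-harmonic limit the VCD rotational strength of mode k is the
  closed form R_k ∝ (P·ℓ_k)·(M_lab·ℓ_k), so band positions, signs and
  intensity ratios of the full pipeline can be checked against analytic
  values.

* :class:`RotorFixture` — a 5-atom methyl-like toy whose three hydrogens
  undergo Langevin torsional dynamics on a 3-fold potential, hopping
  between three chemically equivalent minima.  It exercises the
  permutation expansion of the reference set and the continuity of the
  evolved tensors through minima hops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .matching import MetricFamily, MetricSpec
from .reference import (
    PermutationGenerator,
    ReferenceStructure,
    expand_equivalent_minima,
    gauge_transform_aat,
)
from .spectra import quantum_correction
from .trajectory import Trajectory
from .units import KB_AMU_A2_FS2, wavenumber_to_angular_fs

__all__ = [
    "HarmonicModel",
    "random_harmonic_model",
    "generate_harmonic_trajectory",
    "analytic_rotational_strengths",
    "analytic_dipole_strengths",
    "predicted_band_integrals",
    "RotorFixture",
    "generate_rotor_fixture",
]


@dataclass
class HarmonicModel:
    """Normal-mode model with assigned constant tensors.

    ``modes`` holds K mass-weighted orthonormal displacement vectors of
    shape ``(K, n_atoms, 3)``; the Cartesian displacement of mode k is
    ℓ_k[i] = modes[k, i] / √m_i.  Frequencies in cm⁻¹.
    """

    masses: np.ndarray
    x_eq: np.ndarray  # (n_atoms, 3), Å
    frequencies: np.ndarray  # (K,), cm⁻¹
    modes: np.ndarray  # (K, n_atoms, 3), mass-weighted, orthonormal
    apt: np.ndarray  # (n_atoms, 3, 3)
    aat_local: np.ndarray  # (n_atoms, 3, 3)
    temperature: float = 300.0
    elements: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, float)
        self.x_eq = np.asarray(self.x_eq, float)
        self.frequencies = np.atleast_1d(np.asarray(self.frequencies, float))
        self.modes = np.asarray(self.modes, float)
        K, n = self.modes.shape[0], self.x_eq.shape[0]
        if (self.frequencies <= 0).any():
            raise ValueError("mode frequencies must be positive")
        if not 1 <= K <= max(3 * n - 6, 1):
            raise ValueError(f"need 1 ≤ K ≤ 3N−6 modes, got K={K}, N={n}")
        gram = np.einsum("kix,lix->kl", self.modes, self.modes)
        if not np.allclose(gram, np.eye(K), atol=1e-10):
            raise ValueError("mode vectors must be orthonormal (mass-weighted)")
        if not self.elements:
            self.elements = ["X"] * n

    @property
    def n_atoms(self) -> int:
        return self.x_eq.shape[0]

    @property
    def cart_modes(self) -> np.ndarray:
        """Mass-unweighted Cartesian displacements ℓ_k, shape (K, n, 3)."""
        return self.modes / np.sqrt(self.masses)[None, :, None]

    def reference_structure(self, label: str = "eq") -> ReferenceStructure:
        return ReferenceStructure(
            label=label,
            geometry=self.x_eq,
            elements=list(self.elements),
            apt=self.apt,
            aat_local=self.aat_local,
        )


def _orthonormal_modes(
    rng: np.random.Generator, masses: np.ndarray, x_eq: np.ndarray, K: int
) -> np.ndarray:
    """Random mass-weighted modes orthogonal to rigid translations/rotations."""
    n = masses.size
    sm = np.sqrt(masses)
    rigid = []
    for ax in range(3):  # translations
        t = np.zeros((n, 3))
        t[:, ax] = sm
        rigid.append(t.ravel())
    com = masses @ x_eq / masses.sum()
    disp = x_eq - com
    for ax in range(3):  # infinitesimal rotations
        e = np.zeros(3)
        e[ax] = 1.0
        r = np.cross(e, disp) * sm[:, None]
        if np.linalg.norm(r) > 1e-10:
            rigid.append(r.ravel())
    Q = np.linalg.qr(np.array(rigid).T)[0]
    raw = rng.standard_normal((3 * n, K))
    raw -= Q @ (Q.T @ raw)
    vib = np.linalg.qr(raw)[0]
    return vib.T.reshape(K, n, 3)


def random_harmonic_model(
    n_atoms: int,
    frequencies: Sequence[float],
    seed: int,
    temperature: float = 300.0,
    tensor_scale: float = 1.0,
) -> HarmonicModel:
    """A seeded random but valid harmonic model.

    Geometry, vibrational modes and APT/AAT tensors are drawn from the
    seeded generator; modes are orthogonal to rigid translations and
    rotations so the dynamics is purely vibrational.
    """
    rng = np.random.default_rng(seed)
    masses = rng.uniform(1.0, 16.0, n_atoms)
    x_eq = rng.uniform(-2.0, 2.0, (n_atoms, 3))
    K = len(frequencies)
    modes = _orthonormal_modes(rng, masses, x_eq, K)
    apt = rng.standard_normal((n_atoms, 3, 3)) * tensor_scale
    aat = rng.standard_normal((n_atoms, 3, 3)) * tensor_scale
    return HarmonicModel(
        masses=masses,
        x_eq=x_eq,
        frequencies=np.asarray(frequencies, float),
        modes=modes,
        apt=apt,
        aat_local=aat,
        temperature=temperature,
    )


def generate_harmonic_trajectory(
    model: HarmonicModel, n_steps: int, dt: float, seed: int
) -> Trajectory:
    """Classical-equipartition harmonic trajectory with exact velocities.

    x(t) = x_eq + Σ_k (A_k/√m_i) l_k cos(ω_k t + φ_k) with amplitude
    A_k = √(2 k_B T)/ω_k (mean mode energy k_B T, time-averaged kinetic
    energy k_B T/2) and independent uniform random phases.  ``dt`` must
    resolve the fastest mode with at least 20 steps per period.
    """
    omegas = np.array([wavenumber_to_angular_fs(f) for f in model.frequencies])
    fastest_period = 2 * np.pi / omegas.max()
    if dt > fastest_period / 20:
        raise ValueError(
            f"dt = {dt} fs too large: fastest mode period {fastest_period:.2f} fs "
            "needs ≥ 20 steps per period"
        )
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2 * np.pi, omegas.size)
    if model.temperature > 0:
        amps = np.sqrt(2 * KB_AMU_A2_FS2 * model.temperature) / omegas
    else:
        amps = np.zeros_like(omegas)
    t = np.arange(n_steps) * dt
    phase_t = omegas[None, :] * t[:, None] + phases[None, :]  # (T, K)
    cart = model.cart_modes  # (K, n, 3)
    pos = model.x_eq[None] + np.einsum(
        "tk,k,kix->tix", np.cos(phase_t), amps, cart, optimize=True
    )
    vel = np.einsum(
        "tk,k,kix->tix", -np.sin(phase_t), amps * omegas, cart, optimize=True
    )
    return Trajectory(
        positions=pos,
        dt=dt,
        elements=list(model.elements),
        masses=model.masses,
        velocities=vel,
    )


def analytic_rotational_strengths(
    model: HarmonicModel, origin: Sequence[float] = (0.0, 0.0, 0.0)
) -> np.ndarray:
    """Double-harmonic rotational strengths R_k ∝ (P·ℓ_k)·(M_lab·ℓ_k).

    M_lab is assembled from the local-gauge AAT at the equilibrium
    geometry via the distributed-origin transfer.  The proportionality
    constant matches the pipeline's arbitrary-unit convention, so only
    signs and ratios are certified quantities.
    """
    aat_lab = gauge_transform_aat(model.aat_local, model.apt, model.x_eq, origin)
    cart = model.cart_modes
    p = np.einsum("iuw,kiw->ku", model.apt, cart)
    m = np.einsum("iuw,kiw->ku", aat_lab, cart)
    return np.einsum("ku,ku->k", p, m)


def analytic_dipole_strengths(model: HarmonicModel) -> np.ndarray:
    """Double-harmonic IR strengths |P·ℓ_k|² (arbitrary units)."""
    p = np.einsum("iuw,kiw->ku", model.apt, model.cart_modes)
    return np.einsum("ku,ku->k", p, p)


def predicted_band_integrals(
    model: HarmonicModel,
    channel: str = "vcd",
    correction: str = "harmonic_qcf",
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Expected band integrals of the pipeline spectrum, up to one common factor.

    For mode k with equipartition amplitude A_k² = 2k_BT/ω_k², the
    derivative correlations are C_vcd(τ) = −k_BT·ω_k·R_k·sin(ω_k τ) and
    C_ir(τ) = k_BT·|p_k|²·cos(ω_k τ); with a common window the integral
    over a band is proportional to QCF(ω_k)·ω_k·R_k (VCD) and
    QCF(ω_k)·|p_k|² (IR).
    """
    qcf = quantum_correction(model.frequencies, model.temperature, correction)
    omegas = np.array([wavenumber_to_angular_fs(f) for f in model.frequencies])
    if channel == "vcd":
        return qcf * omegas * analytic_rotational_strengths(model, origin)
    if channel == "ir":
        return qcf * analytic_dipole_strengths(model)
    raise ValueError(f"unknown channel {channel!r}")


# ---------------------------------------------------------------------------
# methyl-rotor toy


_J_Z = np.array([[0.0, 1.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])


def _rot_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass
class RotorFixture:
    """3-fold torsional rotor riding a planar 5-atom methyl-like frame.

    The potential is V(θ) = (V₃/2)(1 − cos 3θ) with three chemically
    equivalent minima at θ = 0°, 120°, 240° related by the cyclic
    permutation of the hydrogens.  Langevin dynamics on θ at the given
    temperature produces hops between the wells.  The default barrier,
    7·10⁻⁴ amu·Å²/fs² (≈ 1.7 kcal/mol), at 600 K gives a well-activated
    hopping regime, mirroring how methyl large-amplitude motions switch
    on at elevated temperature.

    The geometry is planar: a central C, a light off-axis anchor atom,
    and the three H on a ring.  The anchor breaks the ring's rotational
    symmetry twice over — it makes the anchor–H distance metric resolve
    the three wells, and it gives the mass-weighted superposition a
    competing 180°-flip branch, so that evolving tensors from a *single*
    reference exhibits a genuine frame-to-frame discontinuity when the
    fit switches branch, while the full 3-member reducible set hands the
    frame over smoothly between references.

    Per-atom tensors are dominantly axisymmetric about the rotor axis
    (diag(d, d, d′) + λ·ε_z, reflecting the approximate local symmetry
    of X–H moieties) plus a random anisotropic part of norm ``aniso``;
    the three hydrogen blocks are one base block conjugated by each
    hydrogen's ring position, which encodes their chemical equivalence —
    the permuted reference tensors then coincide exactly with the
    covariant construction at the other minima.
    """

    barrier: float = 7.0e-4  # V₃, amu·Å²/fs²
    temperature: float = 600.0
    friction: float = 5.0e-3  # fs⁻¹
    seed: int = 0
    radius: float = 1.0  # H ring radius, Å
    lam: float = 0.3  # axial antisymmetric tensor weight
    aniso: float = 0.8  # norm of the random anisotropic tensor part
    sigma: float = 0.5  # metric width, Å (between thermal spread and well gap)

    #: atom layout: [C, light off-axis anchor, H, H, H]
    MASSES = np.array([12.011, 1.0, 1.008, 1.008, 1.008])
    ELEMENTS = ["C", "X", "H", "H", "H"]
    H_IDX = (2, 3, 4)

    def geometry(self, theta: float | np.ndarray) -> np.ndarray:
        """Atomic positions for torsional angle(s) θ; (…, 5, 3)."""
        theta = np.asarray(theta, float)
        out = np.zeros(theta.shape + (5, 3))
        out[..., 1, 0] = 1.5
        for k in range(3):
            ang = theta + 2 * np.pi * k / 3
            out[..., 2 + k, 0] = self.radius * np.cos(ang)
            out[..., 2 + k, 1] = self.radius * np.sin(ang)
        return out

    @property
    def inertia(self) -> float:
        return 3 * 1.008 * self.radius**2

    def generator(self) -> PermutationGenerator:
        return PermutationGenerator(cycles=[self.H_IDX])

    def metric_spec(self) -> MetricSpec:
        """Anchor–hydrogen distance family; resolves the three wells."""
        return MetricSpec(
            families=[
                MetricFamily(
                    type="interatomic_distance",
                    atoms=[(1, 2), (1, 3), (1, 4)],
                    sigma=self.sigma,
                    name="anchor_H",
                )
            ]
        )

    def _tensor_set(self, rng: np.random.Generator) -> np.ndarray:
        t = np.zeros((5, 3, 3))
        for atom in (0, 1):  # skeleton blocks
            A = rng.standard_normal((3, 3))
            A *= self.aniso / np.linalg.norm(A)
            d1, d2 = rng.uniform(0.6, 1.4, 2)
            t[atom] = np.diag([d1, d1, d2]) + rng.uniform(-self.lam, self.lam) * _J_Z + A
        A = rng.standard_normal((3, 3))
        A *= self.aniso / np.linalg.norm(A)
        B = np.diag([1.2, 1.2, 0.8]) + self.lam * _J_Z + A
        for k in range(3):  # ring-covariant hydrogen blocks
            R = _rot_z(2 * np.pi * k / 3)
            t[2 + k] = R @ B @ R.T
        return t

    def reference_set(self) -> tuple[list[ReferenceStructure], MetricSpec]:
        """The 3-member reducible set: θ=0 minimum plus its permutations."""
        rng = np.random.default_rng(self.seed + 12345)
        spec = self.metric_spec()
        base = ReferenceStructure(
            label="min",
            geometry=self.geometry(0.0),
            elements=list(self.ELEMENTS),
            apt=self._tensor_set(rng),
            aat_local=self._tensor_set(rng),
        )
        refs = expand_equivalent_minima([base], [self.generator()], spec)
        return refs, spec


def generate_rotor_fixture(
    fix: RotorFixture, n_steps: int = 12000, dt: float = 1.0
) -> tuple[Trajectory, list[ReferenceStructure], MetricSpec, np.ndarray]:
    """Langevin torsional trajectory plus the reducible reference set.

    Returns ``(trajectory, references, metric_spec, theta)``.  Fails
    explicitly when no inter-well hop occurred within ``n_steps`` —
    such a run cannot exercise the equivalent-minima machinery; raise
    the temperature or the step count.
    """
    rng = np.random.default_rng(fix.seed)
    I = fix.inertia
    kT = KB_AMU_A2_FS2 * fix.temperature
    c1 = np.exp(-fix.friction * dt)
    c2 = np.sqrt(kT / I * (1 - c1**2))
    theta = np.empty(n_steps)
    th = rng.uniform(-np.pi / 6, np.pi / 6)
    om = rng.normal(0.0, np.sqrt(kT / I))

    def force(t):
        return -1.5 * fix.barrier * np.sin(3 * t)

    for s in range(n_steps):  # BAOAB splitting
        om += 0.5 * dt * force(th) / I
        th += 0.5 * dt * om
        om = c1 * om + c2 * rng.standard_normal()
        th += 0.5 * dt * om
        om += 0.5 * dt * force(th) / I
        theta[s] = th

    wells = np.mod(np.rint(theta / (2 * np.pi / 3)), 3).astype(int)
    if np.all(wells == wells[0]):
        raise RuntimeError(
            "rotor fixture produced no inter-well hop; raise the temperature "
            "or n_steps (barrier ≫ k_B T makes hops exponentially rare)"
        )
    traj = Trajectory(
        positions=fix.geometry(theta),
        dt=dt,
        elements=list(RotorFixture.ELEMENTS),
        masses=RotorFixture.MASSES.copy(),
    )
    refs, spec = fix.reference_set()
    return traj, refs, spec, theta


def well_indices(theta: np.ndarray) -> np.ndarray:
    """Nearest 3-fold well index (0, 1, 2) for each torsion angle."""
    return np.mod(np.rint(np.asarray(theta) / (2 * np.pi / 3)), 3).astype(int)


def tensor_continuity(apt_series: np.ndarray, wells: np.ndarray) -> tuple[float, float]:
    """Continuity statistic for an evolved tensor series.

    Returns ``(max_jump, intra_well_p95)``: the largest frame-to-frame
    Frobenius jump of the whole-system tensor anywhere in the series,
    and the 95th percentile of the jumps between frames that stay within
    one well.  A smooth evolution keeps the maximum within a small
    multiple of the intra-well scale; a branch discontinuity shows up as
    a jump one to two orders of magnitude above it.
    """
    flat = apt_series.reshape(len(apt_series), -1)
    jumps = np.linalg.norm(flat[1:] - flat[:-1], axis=1)
    intra = jumps[np.diff(wells) == 0]
    return float(jumps.max()), float(np.percentile(intra, 95))
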