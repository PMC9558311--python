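"""Frame↔reference superposition, geometric metrics, and Gaussian weights.

The tensor-evolution scheme needs, at every MD frame and for every
reference structure j, (i) the proper rotation R_j(t) that best overlaps
the reference geometry with the instantaneous one (mass-weighted
quaternion fit, satisfying the Eckart conditions for small displacements)
and (ii) a weight w_j(t) ∈ [0, 1] expressing the probability that the
system is currently vibrating around minimum j.  Weights derive from a
cheap geometric metric d_j — per-family RMS differences of interatomic
distances, angles, torsions or continuous coordination numbers — pushed
through a normalized Gaussian kernel of width σ_c.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "RotationFit",
    "quaternion_fit",
    "fit_rotations_batch",
    "coordination_number",
    "MetricFamily",
    "MetricSpec",
    "evaluate_metric_coordinates",
    "compute_metric",
    "compute_weights",
]


# ---------------------------------------------------------------------------
# quaternion superposition (Horn's closed-form eigenvalue method)


@dataclass
class RotationFit:
    """Result of a mass-weighted rigid superposition.

    ``rotation`` maps the *centered* first argument of the fit onto the
    centered second one; ``rmsd`` is the mass-weighted root residual in Å.
    """

    rotation: np.ndarray  # (3, 3), proper orthogonal
    rmsd: float


def _quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrices from unit quaternions (w, x, y, z); batched."""
    w, x, y, z = np.moveaxis(q, -1, 0)
    return np.stack(
        [
            np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], -1),
            np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], -1),
            np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], -1),
        ],
        axis=-2,
    )


def _horn_K(S: np.ndarray) -> np.ndarray:
    """Horn's symmetric 4×4 key matrix from correlation matrices S (…,3,3)."""
    Sxx, Sxy, Sxz = S[..., 0, 0], S[..., 0, 1], S[..., 0, 2]
    Syx, Syy, Syz = S[..., 1, 0], S[..., 1, 1], S[..., 1, 2]
    Szx, Szy, Szz = S[..., 2, 0], S[..., 2, 1], S[..., 2, 2]
    tr = Sxx + Syy + Szz
    K = np.empty(S.shape[:-2] + (4, 4))
    K[..., 0, 0] = tr
    K[..., 0, 1] = K[..., 1, 0] = Syz - Szy
    K[..., 0, 2] = K[..., 2, 0] = Szx - Sxz
    K[..., 0, 3] = K[..., 3, 0] = Sxy - Syx
    K[..., 1, 1] = Sxx - Syy - Szz
    K[..., 1, 2] = K[..., 2, 1] = Sxy + Syx
    K[..., 1, 3] = K[..., 3, 1] = Szx + Sxz
    K[..., 2, 2] = Syy - Sxx - Szz
    K[..., 2, 3] = K[..., 3, 2] = Syz + Szy
    K[..., 3, 3] = Szz - Sxx - Syy
    return K


def _check_nondegenerate(centered: np.ndarray, masses: np.ndarray) -> None:
    s = np.linalg.svd(centered * np.sqrt(masses)[:, None], compute_uv=False)
    if s[1] <= 1e-10 * max(s[0], 1.0):
        raise ValueError(
            "degenerate (collinear or point-like) geometry: the fitted "
            "rotation is not uniquely determined"
        )


def quaternion_fit(
    coords: np.ndarray, ref_coords: np.ndarray, masses: np.ndarray
) -> RotationFit:
    """Proper rotation superposing ``coords`` onto ``ref_coords``.

    Minimizes Σ_i m_i |R·(x_i − x̄) − (r_i − r̄)|² over proper rotations
    via Horn's quaternion eigenvalue method; never returns a reflection,
    even when the target is a mirror image (the best *proper* rotation is
    returned with a nonzero residual instead).
    """
    coords = np.asarray(coords, float)
    ref_coords = np.asarray(ref_coords, float)
    masses = np.asarray(masses, float)
    if coords.shape != ref_coords.shape or coords.shape[0] != masses.shape[0]:
        raise ValueError("coords, ref_coords and masses must be atom-aligned")
    if coords.shape[0] < 3:
        raise ValueError("at least 3 atoms are required for a rotation fit")
    wtot = masses.sum()
    a = coords - masses @ coords / wtot
    b = ref_coords - masses @ ref_coords / wtot
    _check_nondegenerate(a, masses)
    S = np.einsum("i,ix,iy->xy", masses, a, b)
    evals, evecs = np.linalg.eigh(_horn_K(S))
    q = evecs[:, -1]
    R = _quaternion_to_matrix(q)
    resid = np.einsum("i,ix->", masses, (a @ R.T - b) ** 2)
    rmsd = float(np.sqrt(max(resid, 0.0) / wtot))
    return RotationFit(rotation=R, rmsd=rmsd)


def fit_rotations_batch(
    frames: np.ndarray, ref_coords: np.ndarray, masses: np.ndarray
) -> np.ndarray:
    """Vectorized quaternion fit of many frames onto one reference.

    ``frames`` is ``(n_frames, n_atoms, 3)``; returns ``(n_frames, 3, 3)``
    rotations, each mapping the centered frame onto the centered
    reference (same convention as :func:`quaternion_fit`).
    """
    frames = np.asarray(frames, float)
    ref_coords = np.asarray(ref_coords, float)
    masses = np.asarray(masses, float)
    wtot = masses.sum()
    b = ref_coords - masses @ ref_coords / wtot
    _check_nondegenerate(b, masses)
    com = np.einsum("a,fax->fx", masses, frames) / wtot
    a = frames - com[:, None, :]
    S = np.einsum("i,fix,iy->fxy", masses, a, b)
    _evals, evecs = np.linalg.eigh(_horn_K(S))
    return _quaternion_to_matrix(evecs[..., -1])


# ---------------------------------------------------------------------------
# metric coordinates


def coordination_number(
    r: float | np.ndarray, R0: float, exponents: tuple[int, int] = (6, 12)
) -> float | np.ndarray:
    """Continuous coordination number (1−(r/R0)ⁿ)/(1−(r/R0)ᵐ).

    Smoothly switches from 1 (r → 0) to 0 (r → ∞); at r = R0 the removable
    singularity has the limit n/m.  Requires 0 < n < m.
    """
    n, m = exponents
    if not (0 < n < m):
        raise ValueError(f"exponents must satisfy 0 < n < m, got {exponents}")
    if R0 <= 0:
        raise ValueError("R0 must be positive")
    x = np.asarray(r, float) / R0
    eps = x - 1.0
    near = np.abs(eps) < 1e-6
    safe = np.where(near, 2.0, x)  # dummy away from the singular point
    val = (1.0 - safe**n) / (1.0 - safe**m)
    series = (n / m) * (1.0 + 0.5 * (n - m) * eps)  # Taylor limit at x→1
    out = np.where(near, series, val)
    return float(out) if np.isscalar(r) else out


@dataclass
class MetricFamily:
    """One coordinate family of a metric: same-type internal coordinates.

    ``atoms`` holds index tuples *within the fragment*: pairs for
    distances and coordination numbers, triples for angles, quadruples
    for torsions.  ``sigma`` is the Gaussian width in the family's units
    (Å, or radians for angles/torsions); ``None`` requests the automatic
    half-minimal-inter-reference-distance default at load time.
    """

    type: str
    atoms: list[tuple[int, ...]]
    sigma: float | None = None
    r0: float = 3.0
    exponents: tuple[int, int] = (6, 12)
    name: str = ""

    _ARITY = {
        "interatomic_distance": 2,
        "bond_angle": 3,
        "torsion": 4,
        "coordination_number": 2,
    }

    def __post_init__(self) -> None:
        if self.type not in self._ARITY:
            raise ValueError(f"unknown metric family type {self.type!r}")
        arity = self._ARITY[self.type]
        self.atoms = [tuple(int(i) for i in t) for t in self.atoms]
        for t in self.atoms:
            if len(t) != arity:
                raise ValueError(
                    f"{self.type} coordinates take {arity} atoms, got {t}"
                )
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not self.name:
            self.name = self.type

    @property
    def is_angular(self) -> bool:
        return self.type in ("bond_angle", "torsion")


@dataclass
class MetricSpec:
    """A collection of metric families defining the distance d_j."""

    families: list[MetricFamily]

    def __post_init__(self) -> None:
        names = [f.name for f in self.families]
        if len(set(names)) != len(names):
            raise ValueError("metric family names must be unique")


def _angles(p0, p1, p2):
    u = p0 - p1
    v = p2 - p1
    cosang = np.einsum("...x,...x", u, v) / (
        np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1)
    )
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def _torsions(p0, p1, p2, p3):
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=-1, keepdims=True))
    x = np.einsum("...x,...x", n1, n2)
    y = np.einsum("...x,...x", m1, n2)
    norm = np.linalg.norm(n1, axis=-1) * np.linalg.norm(n2, axis=-1)
    bad = norm < 1e-12
    if np.any(bad):
        warnings.warn(
            "torsion undefined for collinear atoms; coordinate set to 0",
            RuntimeWarning,
            stacklevel=3,
        )
    return np.where(bad, 0.0, np.arctan2(y, x))


def evaluate_metric_coordinates(
    coords: np.ndarray, spec: MetricSpec
) -> dict[str, np.ndarray]:
    """Values of every family's coordinates for one or many configurations.

    ``coords`` is ``(..., n_atoms, 3)`` (fragment-local indexing, optional
    leading batch axes such as time); angles and torsions are returned in
    radians, distances in Å, coordination numbers dimensionless.  The
    per-family result has shape ``(..., n_coordinates)``.
    """
    coords = np.asarray(coords, float)
    out: dict[str, np.ndarray] = {}
    for fam in spec.families:
        idx = np.array(fam.atoms)
        p = [coords[..., idx[:, k], :] for k in range(idx.shape[1])]
        if fam.type == "interatomic_distance":
            vals = np.linalg.norm(p[0] - p[1], axis=-1)
        elif fam.type == "coordination_number":
            r = np.linalg.norm(p[0] - p[1], axis=-1)
            vals = coordination_number(r, fam.r0, fam.exponents)
        elif fam.type == "bond_angle":
            vals = _angles(p[0], p[1], p[2])
        else:  # torsion
            vals = _torsions(p[0], p[1], p[2], p[3])
        out[fam.name] = np.asarray(vals, float)
    return out


def _wrap_angle(delta: np.ndarray) -> np.ndarray:
    """Wrap angular differences onto (−π, π]."""
    return np.pi - np.mod(np.pi - delta, 2.0 * np.pi)


def compute_metric(
    frame_coords: np.ndarray,
    ref,
    spec: MetricSpec,
) -> dict[str, float]:
    """Per-family distance d_j^x between a frame and one reference.

    ``ref`` may be a reference-structure object (stored ``metric_values``
    are used when present, its ``geometry`` otherwise) or a bare
    ``(n_atoms, 3)`` geometry.  Each family contributes the root of the
    *mean* squared coordinate difference, so σ_c is scale-free with
    respect to the number of coordinates in the family; angular families
    are differenced on the circle.
    """
    frame_vals = evaluate_metric_coordinates(frame_coords, spec)
    ref_vals = _reference_metric_values(ref, spec)
    out: dict[str, float] = {}
    for fam in spec.families:
        delta = frame_vals[fam.name] - ref_vals[fam.name]
        if fam.is_angular:
            delta = _wrap_angle(delta)
        out[fam.name] = float(np.sqrt(np.mean(delta**2)))
    return out


def _reference_metric_values(ref, spec: MetricSpec) -> Mapping[str, np.ndarray]:
    stored = getattr(ref, "metric_values", None)
    if stored and all(f.name in stored for f in spec.families):
        return {k: np.asarray(v, float) for k, v in stored.items()}
    geom = getattr(ref, "geometry", ref)
    return evaluate_metric_coordinates(np.asarray(geom, float), spec)


# ---------------------------------------------------------------------------
# Gaussian weights


def compute_weights(
    distances: Sequence[Mapping[str, float]] | np.ndarray,
    spec: MetricSpec,
) -> np.ndarray:
    """Normalized Gaussian weights over references.

    w_j ∝ ∏_x exp(−(d_j^x)² / (2 σ_x²)), normalized to Σ_j w_j = 1.
    Evaluated in log space (shift by the smallest aggregate squared
    distance before exponentiating), so frames far from every reference
    still yield a defined weight vector: in the deep-underflow limit all
    weight concentrates on the nearest reference, ties broken towards the
    lowest index.
    """
    sigmas = []
    for fam in spec.families:
        if fam.sigma is None:
            raise ValueError(
                f"family {fam.name!r} has no sigma; call resolve_sigmas() "
                "or set one explicitly"
            )
        sigmas.append(fam.sigma)
    if isinstance(distances, np.ndarray):
        d = np.atleast_2d(np.asarray(distances, float))
    else:
        d = np.array(
            [[dj[f.name] for f in spec.families] for dj in distances], float
        )
    if d.shape[0] < 1:
        raise ValueError("at least one reference is required")
    z = np.einsum("jx->j", (d / np.asarray(sigmas)) ** 2)
    logw = -0.5 * (z - z.min())
    w = np.exp(logw)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:  # pragma: no cover - guard only
        w = np.zeros_like(z)
        w[int(np.argmin(z))] = 1.0
        total = 1.0
    return w / total


def resolve_sigmas(spec: MetricSpec, references: Iterable) -> MetricSpec:
    """Fill in unset family widths from the reference set.

    The default is half the minimal nonzero inter-reference distance in
    each family (circular for angles), which guarantees the kernel can
    resolve neighbouring references.  References must expose ``geometry``
    or stored ``metric_values``.
    """
    refs = list(references)
    vals = [_reference_metric_values(r, spec) for r in refs]
    for k, fam in enumerate(spec.families):
        if fam.sigma is not None:
            continue
        dmin = np.inf
        for i in range(len(refs)):
            for j in range(i + 1, len(refs)):
                delta = np.asarray(vals[i][fam.name]) - np.asarray(vals[j][fam.name])
                if fam.is_angular:
                    delta = _wrap_angle(delta)
                d = float(np.sqrt(np.mean(delta**2)))
                if d > 1e-12:
                    dmin = min(dmin, d)
        if not np.isfinite(dmin):
            raise ValueError(
                f"cannot auto-set sigma for family {fam.name!r}: fewer than "
                "two distinct references; set sigma explicitly"
            )
        fam.sigma = 0.5 * dmin
    return spec
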