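"""Reference-structure tensor library.

Each reference structure is one minimum of the potential energy surface
carrying the electronic-structure tensors the evolution scheme
interpolates: the Atomic Polar Tensor (APT, per-atom 3×3 blocks
P_uw = ∂μ_u/∂ξ_w) and the Atomic Axial Tensor (AAT, per-atom 3×3 blocks
M_uw = ∂m_u/∂v_w) stored in the distributed-origin (atom-centered)
gauge.  The AAT is kept real-valued: the imaginary unit of the quantum
tensor is absorbed into the sine-transform convention of the spectra
module, so everything downstream is real arithmetic.

Sets are exchanged as versioned JSON documents (schema ``awv-refset-v1``)
rather than by parsing quantum-chemistry output files.

Chemically equivalent minima (e.g. the three indistinguishable wells of
a methyl torsion) are generated from an *irreducible* set by permuting
equivalent atoms — geometry rows and tensor atom-blocks alike — giving
the full *reducible* set at no additional electronic-structure cost.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .units import BOHR_A, C_AU
from .matching import MetricFamily, MetricSpec, evaluate_metric_coordinates

__all__ = [
    "ReferenceStructure",
    "PermutationGenerator",
    "load_reference_set",
    "load_refset",
    "save_reference_set",
    "gauge_transform_aat",
    "expand_equivalent_minima",
    "LEVI_CIVITA",
    "GAUGE_PREFACTOR",
]

FORMAT_VERSION = "awv-refset-v1"

#: ε_αγδ, the alternating (Levi-Civita) tensor.
LEVI_CIVITA = np.zeros((3, 3, 3))
for _i, _j, _k in itertools.permutations(range(3)):
    LEVI_CIVITA[_i, _j, _k] = (_j - _i) * (_k - _j) * (_k - _i) / 2

#: Distributed-origin → common-origin transfer constant, 1/(4c) in atomic
#: units (positions are converted Å → bohr inside the transfer).
GAUGE_PREFACTOR = 1.0 / (4.0 * C_AU)


@dataclass
class ReferenceStructure:
    """One PES minimum: geometry + APT + local-gauge AAT (+ metric values).

    ``metric_values`` caches the metric-coordinate values {γ_k} evaluated
    at creation time, keyed by family name; when absent they are derived
    from ``geometry`` on demand by the matching module.
    """

    label: str
    geometry: np.ndarray  # (n_atoms, 3), Å
    elements: list[str]
    apt: np.ndarray  # (n_atoms, 3, 3)
    aat_local: np.ndarray  # (n_atoms, 3, 3), distributed-origin gauge
    metric_values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.geometry = np.asarray(self.geometry, float)
        self.apt = np.asarray(self.apt, float)
        self.aat_local = np.asarray(self.aat_local, float)
        n = self.geometry.shape[0]
        if self.geometry.shape != (n, 3):
            raise ValueError(f"{self.label}: geometry must be (n_atoms, 3)")
        for name, t in (("apt", self.apt), ("aat_local", self.aat_local)):
            if t.shape != (n, 3, 3):
                raise ValueError(
                    f"{self.label}: {name} shape {t.shape} does not match "
                    f"{n} atoms (expected {(n, 3, 3)})"
                )
            if not np.isfinite(t).all():
                raise ValueError(f"{self.label}: {name} contains non-finite values")
        if not np.isfinite(self.geometry).all():
            raise ValueError(f"{self.label}: geometry contains non-finite values")
        if len(self.elements) != n:
            raise ValueError(f"{self.label}: elements length mismatch")
        self.metric_values = {
            k: np.asarray(v, float) for k, v in self.metric_values.items()
        }

    @property
    def n_atoms(self) -> int:
        return self.geometry.shape[0]


@dataclass
class PermutationGenerator:
    """A symmetry operation mapping a minimum onto an equivalent one.

    ``cycles`` lists disjoint atom-index cycles; the cycle (a, b, c)
    sends atom a's role to b, b's to c, and c's to a (a 3-fold methyl
    rotation is one 3-cycle of the hydrogen indices).  ``order`` is the
    size of the cyclic group the operation generates.
    """

    cycles: list[tuple[int, ...]]

    def __post_init__(self) -> None:
        self.cycles = [tuple(int(i) for i in c) for c in self.cycles]
        seen: set[int] = set()
        for c in self.cycles:
            if len(c) < 2 or len(set(c)) != len(c):
                raise ValueError(f"invalid cycle {c}")
            if seen & set(c):
                raise ValueError("cycles must be disjoint")
            seen |= set(c)

    @property
    def order(self) -> int:
        return int(np.lcm.reduce([len(c) for c in self.cycles]))

    def source_indices(self, n_atoms: int, power: int = 1) -> np.ndarray:
        """Index array ``src`` with ``new[i] = old[src[i]]`` for σ^power."""
        src = np.arange(n_atoms)
        for _ in range(power % self.order):
            step = np.arange(n_atoms)
            for c in self.cycles:
                for k, atom in enumerate(c):
                    # atom c[k]'s content moves to c[k+1]: target gets source
                    step[c[(k + 1) % len(c)]] = atom
            src = src[step]
        return src


# ---------------------------------------------------------------------------
# JSON exchange format


@dataclass
class RefSet:
    """A loaded reference set plus its frozen metric specification."""

    structures: list[ReferenceStructure]
    elements: list[str]
    metric_spec: MetricSpec | None = None


def _metric_spec_to_json(spec: MetricSpec) -> list[dict]:
    return [
        {
            "name": f.name,
            "type": f.type,
            "atoms": [list(t) for t in f.atoms],
            "sigma": f.sigma,
            "r0": f.r0,
            "exponents": list(f.exponents),
        }
        for f in spec.families
    ]


def metric_spec_from_json(block: Sequence[dict]) -> MetricSpec:
    fams = []
    for b in block:
        fams.append(
            MetricFamily(
                type=b["type"],
                atoms=[tuple(t) for t in b["atoms"]],
                sigma=b.get("sigma"),
                r0=b.get("r0", 3.0),
                exponents=tuple(b.get("exponents", (6, 12))),
                name=b.get("name", ""),
            )
        )
    return MetricSpec(families=fams)


def save_reference_set(
    path: str | Path,
    structures: Sequence[ReferenceStructure],
    metric_spec: MetricSpec | None = None,
) -> None:
    """Write a reference set as an ``awv-refset-v1`` JSON document."""
    structures = list(structures)
    doc = {
        "format_version": FORMAT_VERSION,
        "elements": list(structures[0].elements),
        "metric_spec": _metric_spec_to_json(metric_spec) if metric_spec else None,
        "structures": [
            {
                "label": s.label,
                "geometry": s.geometry.tolist(),
                "apt": s.apt.tolist(),
                "aat_local": s.aat_local.tolist(),
                "metric_values": {k: v.tolist() for k, v in s.metric_values.items()},
            }
            for s in structures
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_refset(path: str | Path) -> RefSet:
    """Load and validate an ``awv-refset-v1`` JSON document."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"unsupported reference-set format {doc.get('format_version')!r}"
        )
    elements = list(doc["elements"])
    structures = []
    labels: set[str] = set()
    for blk in doc["structures"]:
        s = ReferenceStructure(
            label=blk["label"],
            geometry=np.array(blk["geometry"], float),
            elements=elements,
            apt=np.array(blk["apt"], float),
            aat_local=np.array(blk["aat_local"], float),
            metric_values={
                k: np.array(v, float)
                for k, v in (blk.get("metric_values") or {}).items()
            },
        )
        if s.label in labels:
            raise ValueError(f"duplicate reference label {s.label!r}")
        labels.add(s.label)
        structures.append(s)
    if not structures:
        raise ValueError(f"no structures in {path}")
    n0 = structures[0].n_atoms
    for s in structures:
        if s.n_atoms != n0:
            raise ValueError(
                f"structure {s.label!r} has {s.n_atoms} atoms, expected {n0}"
            )
    spec = (
        metric_spec_from_json(doc["metric_spec"]) if doc.get("metric_spec") else None
    )
    return RefSet(structures=structures, elements=elements, metric_spec=spec)


def load_reference_set(path: str | Path) -> list[ReferenceStructure]:
    """Load a reference set, returning the validated structure list."""
    return load_refset(path).structures


# ---------------------------------------------------------------------------
# gauge transfer


def gauge_transform_aat(
    aat_local: np.ndarray,
    apt: np.ndarray,
    positions: np.ndarray,
    origin: np.ndarray | Sequence[float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Transfer distributed-origin AAT blocks to a common laboratory origin.

    M_lab[i]_αβ = M_local[i]_αβ + κ · ε_αγδ · r[i]_γ · P[i]_δβ, with
    r = (positions − origin) in bohr and κ = 1/(4c) (atomic units, c the
    speed of light).  With r = 0, or with a vanishing APT, the local
    blocks pass through unchanged.
    """
    aat_local = np.asarray(aat_local, float)
    apt = np.asarray(apt, float)
    positions = np.asarray(positions, float)
    if aat_local.shape != apt.shape or positions.shape != aat_local.shape[:-2] + (3,):
        raise ValueError("aat_local, apt and positions must be atom-aligned")
    r = (positions - np.asarray(origin, float)) / BOHR_A
    corr = GAUGE_PREFACTOR * np.einsum(
        "agd,...g,...db->...ab", LEVI_CIVITA, r, apt
    )
    return aat_local + corr


# ---------------------------------------------------------------------------
# equivalent-minima expansion


def _permute_structure(
    s: ReferenceStructure, src: np.ndarray, tag: str, metric_spec: MetricSpec | None
) -> ReferenceStructure:
    for i, j in enumerate(src):
        if s.elements[i] != s.elements[j]:
            raise ValueError(
                f"generator permutes atoms of different elements "
                f"({s.elements[j]} → position of {s.elements[i]})"
            )
    geom = s.geometry[src]
    new = ReferenceStructure(
        label=f"{s.label}{tag}",
        geometry=geom,
        elements=list(s.elements),
        apt=s.apt[src],
        aat_local=s.aat_local[src],
        metric_values=(
            evaluate_metric_coordinates(geom, metric_spec) if metric_spec else {}
        ),
    )
    return new


def expand_equivalent_minima(
    irreducible: Sequence[ReferenceStructure],
    generators: Sequence[PermutationGenerator],
    metric_spec: MetricSpec | None = None,
) -> list[ReferenceStructure]:
    """Build the reducible reference set from the irreducible one.

    Every structure is replicated under the direct product of the cyclic
    groups generated by ``generators`` (disjoint atom supports, e.g. one
    3-cycle per methyl rotor), permuting geometry rows and APT/AAT atom
    blocks consistently.  The output has exactly
    ``len(irreducible) × ∏ order(g)`` members — chemically equivalent
    minima are distinct points on the PES, so no deduplication is done.
    Metric values are re-evaluated from the permuted geometry when a
    ``metric_spec`` is given, and left for on-demand evaluation otherwise.
    """
    if not irreducible:
        return []
    if not generators:
        return list(irreducible)
    n_atoms = irreducible[0].n_atoms
    out: list[ReferenceStructure] = []
    powers = itertools.product(*[range(g.order) for g in generators])
    for combo in powers:
        src = np.arange(n_atoms)
        for g, p in zip(generators, combo):
            src = src[g.source_indices(n_atoms, p)]
        tag = "" if not any(combo) else "@" + "-".join(map(str, combo))
        for s in irreducible:
            if any(combo):
                out.append(_permute_structure(s, src, tag, metric_spec))
            else:
                # identity element: still validate element consistency
                out.append(s)
    return out
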