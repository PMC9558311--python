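"""End-to-end orchestration of the AWV protocol from a single config.

The run covers the analysis half of the workflow (the MD production
itself is the user's engine's job): read each replica trajectory,
optionally make molecules whole under periodic boundaries and/or remove
global rotation, differentiate, evolve the tensors fragment-wise from
the reference libraries, form the μ̇/ṁ series, accumulate per-pair
correlation functions, average them over replicas, transform, and write
total/intra/cross spectra with a provenance manifest.

Config is one YAML document; all paths are resolved relative to the
config file's directory.  See the README for the schema.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .evolution import (
    FragmentDefinition,
    evolve_tensors_fragments,
    weighted_derivatives,
)
from .matching import MetricSpec, resolve_sigmas
from .reference import load_refset, metric_spec_from_json
from .spectra import (
    CorrelationFunction,
    Spectrum,
    SpectrumConfig,
    average_replicas,
    spectrum_from_pair_cfs,
)
from .trajectory import (
    Topology,
    finite_difference_derivatives,
    read_xyz_trajectory,
    remove_global_rotation,
    wrap_molecules,
)

logger = logging.getLogger("awv")

#: cross channels whose band-integrated magnitude falls below this
#: fraction of the total are not written to per-channel files (they are
#: always kept in memory for the decomposition identity).
CROSS_WRITE_THRESHOLD = 1e-6


@dataclass
class RunConfig:
    """Validated run configuration (see README for the YAML schema)."""

    trajectories: list[Path]
    dt: float
    molecules: list[list[int]]
    fragments: list[dict[str, Any]]
    spectrum: SpectrumConfig
    output_dir: Path
    seed: int = 0
    remove_rotation: bool = False
    reference_frame: int = 0
    wrap: bool = False
    gauge_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    stride: int = 1
    base_dir: Path = Path(".")
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        doc = yaml.safe_load(path.read_text())
        base = path.parent
        spec_blk = doc.get("spectrum", {}) or {}
        cfg = cls(
            trajectories=[base / p for p in doc["trajectories"]],
            dt=float(doc["dt"]),
            molecules=[list(m) for m in doc["topology"]["molecules"]],
            fragments=list(doc.get("fragments", [])),
            spectrum=SpectrumConfig(**spec_blk),
            output_dir=base / doc.get("output_dir", "awv_out"),
            seed=int(doc.get("seed", 0)),
            remove_rotation=bool(doc.get("remove_rotation", False)),
            reference_frame=int(doc.get("reference_frame", 0)),
            wrap=bool(doc.get("wrap", False)),
            gauge_origin=tuple(doc.get("gauge_origin", (0.0, 0.0, 0.0))),
            stride=int(doc.get("stride", 1)),
            base_dir=base,
            raw=doc,
        )
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def validate_config(cfg: RunConfig) -> dict[str, list[str]]:
    """Cross-reference checks; returns {'errors': [...], 'warnings': [...]}.

    Report-only: callers decide whether to abort.  Checks file existence,
    fragment coverage of every molecule, metric-atom resolvability and
    reference-set consistency; warns where a heuristic σ_c default will
    be used.
    """
    errors: list[str] = []
    warnings: list[str] = []
    for p in cfg.trajectories:
        if not Path(p).exists():
            errors.append(f"trajectory file not found: {p}")
    if not cfg.trajectories:
        errors.append("no trajectory replicas listed")
    n_atoms = sum(len(m) for m in cfg.molecules)
    seen: set[int] = set()
    for m, mol in enumerate(cfg.molecules):
        if seen & set(mol):
            errors.append(f"molecule {m} overlaps a previous molecule")
        seen |= set(mol)
    if seen != set(range(n_atoms)):
        errors.append("topology molecules must cover atoms 0..n_atoms-1")
    for fi, frag in enumerate(cfg.fragments):
        name = frag.get("name", f"fragment{fi}")
        refpath = cfg.base_dir / frag.get("refset", "")
        if not refpath.exists():
            errors.append(f"fragment {name!r}: reference set not found: {refpath}")
            continue
        try:
            refset = load_refset(refpath)
        except Exception as exc:  # noqa: BLE001 - report, don't raise
            errors.append(f"fragment {name!r}: bad reference set: {exc}")
            continue
        mols = frag.get("molecules", "all")
        mol_ids = range(len(cfg.molecules)) if mols == "all" else mols
        for m in mol_ids:
            if m >= len(cfg.molecules):
                errors.append(f"fragment {name!r}: molecule index {m} out of range")
                continue
            local = frag.get("atoms", list(range(len(cfg.molecules[m]))))
            if max(local, default=-1) >= len(cfg.molecules[m]):
                errors.append(
                    f"fragment {name!r}: atom index beyond molecule {m} "
                    f"({len(cfg.molecules[m])} atoms)"
                )
        if refset.metric_spec is None:
            errors.append(f"fragment {name!r}: reference set carries no metric spec")
        else:
            n_frag = len(frag.get("atoms", cfg.molecules[0]))
            for fam in refset.metric_spec.families:
                flat = [i for t in fam.atoms for i in t]
                if max(flat, default=-1) >= n_frag:
                    errors.append(
                        f"fragment {name!r}: metric family {fam.name!r} uses "
                        f"atom index beyond the fragment ({n_frag} atoms)"
                    )
                if fam.sigma is None:
                    warnings.append(
                        f"fragment {name!r}: family {fam.name!r} has no sigma; "
                        "the half-minimal-inter-reference default will be used"
                    )
    # coverage check per molecule
    for m in range(len(cfg.molecules)):
        covered: list[int] = []
        for frag in cfg.fragments:
            mols = frag.get("molecules", "all")
            if mols == "all" or m in mols:
                covered += list(frag.get("atoms", range(len(cfg.molecules[m]))))
        missing = sorted(set(range(len(cfg.molecules[m]))) - set(covered))
        if missing:
            errors.append(
                f"molecule {m}: fragments do not cover atoms {missing}"
            )
    return {"errors": errors, "warnings": warnings}


def _build_fragment_defs(cfg: RunConfig) -> list[list[FragmentDefinition]]:
    """Instantiate per-molecule FragmentDefinition lists from the config."""
    defs: list[list[FragmentDefinition]] = [[] for _ in cfg.molecules]
    for fi, frag in enumerate(cfg.fragments):
        name = frag.get("name", f"fragment{fi}")
        refset = load_refset(cfg.base_dir / frag["refset"])
        if refset.metric_spec is None:
            raise ValueError(f"fragment {name!r}: reference set has no metric spec")
        resolve_sigmas(refset.metric_spec, refset.structures)
        mols = frag.get("molecules", "all")
        mol_ids = range(len(cfg.molecules)) if mols == "all" else mols
        for m in mol_ids:
            atoms = frag.get("atoms", list(range(len(cfg.molecules[m]))))
            defs[m].append(
                FragmentDefinition(
                    name=name,
                    atoms=atoms,
                    references=refset.structures,
                    metric_spec=refset.metric_spec,
                    ref_atoms=frag.get("ref_atoms"),
                    allow_small=bool(frag.get("allow_small", False)),
                )
            )
    return defs


def run_awv(cfg: RunConfig) -> Spectrum:
    """Execute the full protocol; writes outputs and returns the spectrum."""
    report = validate_config(cfg)
    for w in report["warnings"]:
        logger.warning(w)
    if report["errors"]:
        raise ValueError(
            "invalid configuration:\n  " + "\n  ".join(report["errors"])
        )
    topo = Topology(molecules=[np.asarray(m) for m in cfg.molecules])
    frag_defs = _build_fragment_defs(cfg)
    pair_cfs_per_replica: dict[tuple[int, int], list[CorrelationFunction]] = {}
    for r, tpath in enumerate(cfg.trajectories):
        t0 = time.time()
        try:
            traj = read_xyz_trajectory(tpath, dt=cfg.dt)
            if cfg.wrap:
                traj = wrap_molecules(traj, topo)
            if cfg.remove_rotation:
                traj = remove_global_rotation(traj, cfg.reference_frame)
            dv = finite_difference_derivatives(traj)
            tensors = evolve_tensors_fragments(
                traj, topo, frag_defs, frames=dv.frames, stride=cfg.stride
            )
            series = weighted_derivatives(
                tensors, dv.velocities, dv.accelerations, topo, cfg.gauge_origin
            )
            from .spectra import pair_correlations

            for pair, cf in pair_correlations(series, cfg.spectrum.t_max).items():
                pair_cfs_per_replica.setdefault(pair, []).append(cf)
        except Exception as exc:
            raise RuntimeError(
                f"replica {r} ({tpath.name}): {exc}"
            ) from exc
        logger.info("replica %d done in %.1f s", r, time.time() - t0)
    avg_pair_cfs = {
        pair: average_replicas(cfs) for pair, cfs in pair_cfs_per_replica.items()
    }
    spectrum = spectrum_from_pair_cfs(avg_pair_cfs, cfg.spectrum)
    write_outputs(cfg, spectrum, avg_pair_cfs)
    return spectrum


def _write_tsv(path: Path, freq: np.ndarray, intens: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("# wavenumber_cm-1\tintensity_arb\n")
        for f, v in zip(freq, intens):
            fh.write(f"{f:.6f}\t{v:.10e}\n")


def write_outputs(
    cfg: RunConfig,
    spectrum: Spectrum,
    pair_cfs: dict[tuple[int, int], CorrelationFunction] | None = None,
) -> None:
    """Write TSV spectra, an HDF5 bundle, and a JSON manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(out / "vcd_total.tsv", spectrum.frequencies, spectrum.total)
    for m, v in spectrum.intra.items():
        _write_tsv(out / f"vcd_intra_mol{m}.tsv", spectrum.frequencies, v)
    total_scale = float(np.abs(spectrum.total).sum()) or 1.0
    for (m, n), v in spectrum.cross.items():
        if np.abs(v).sum() >= CROSS_WRITE_THRESHOLD * total_scale:
            _write_tsv(out / f"vcd_cross_mol{m}_mol{n}.tsv", spectrum.frequencies, v)
    try:
        import h5py

        with h5py.File(out / "awv_bundle.h5", "w") as h5:
            h5.attrs["config_hash"] = cfg.config_hash()
            h5.attrs["version"] = __version__
            h5.create_dataset("frequencies_cm1", data=spectrum.frequencies)
            h5.create_dataset("vcd_total", data=spectrum.total)
            g = h5.create_group("intra")
            for m, v in spectrum.intra.items():
                g.create_dataset(str(m), data=v)
            g = h5.create_group("cross")
            for (m, n), v in spectrum.cross.items():
                g.create_dataset(f"{m}_{n}", data=v)
            if pair_cfs:
                g = h5.create_group("pair_cfs")
                any_cf = next(iter(pair_cfs.values()))
                g.create_dataset("lags_fs", data=any_cf.lags)
                g.attrs["n_origins"] = any_cf.n_origins
                for (m, n), cf in pair_cfs.items():
                    g.create_dataset(f"{m}_{n}", data=cf.values)
    except OSError as exc:  # pragma: no cover - h5 write failure is non-fatal
        logger.warning("HDF5 bundle not written: %s", exc)
    manifest = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "n_replicas": len(cfg.trajectories),
        "n_molecules": len(cfg.molecules),
        "seed": cfg.seed,
        "spectrum": {
            "temperature_K": cfg.spectrum.temperature,
            "t_max_fs": cfg.spectrum.t_max,
            "window": cfg.spectrum.window,
            "zero_padding": cfg.spectrum.zero_padding,
            "correction": cfg.spectrum.correction,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
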