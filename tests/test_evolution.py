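"""Tensor evolution and the weighted derivative series."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from awv.evolution import (
    FragmentDefinition,
    evolve_tensors_fragments,
    evolve_tensors_global,
    weighted_derivatives,
)
from awv.matching import MetricFamily, MetricSpec
from awv.reference import ReferenceStructure
from awv.trajectory import Topology, Trajectory


def _ref_from(rng, geometry, elements, label="r"):
    n = len(geometry)
    return ReferenceStructure(
        label=label,
        geometry=geometry,
        elements=elements,
        apt=rng.standard_normal((n, 3, 3)),
        aat_local=rng.standard_normal((n, 3, 3)),
    )


@pytest.fixture()
def static_system(rng):
    geom = rng.standard_normal((4, 3)) * 2
    elements = ["C", "O", "H", "H"]
    ref = _ref_from(rng, geom, elements)
    traj = Trajectory(
        positions=np.tile(geom, (8, 1, 1)), dt=1.0, elements=elements
    )
    spec = MetricSpec(
        [
            MetricFamily(
                type="interatomic_distance",
                atoms=[(i, j) for i in range(4) for j in range(i + 1, 4)],
                sigma=0.5,
            )
        ]
    )
    return traj, ref, spec


class TestEvolveGlobal:
    def test_frame_at_reference_returns_reference_tensors(self, static_system):
        traj, ref, spec = static_system
        ts = evolve_tensors_global(traj, [ref], spec)
        assert np.abs(ts.apt - ref.apt).max() < 1e-10
        assert np.abs(ts.aat_local - ref.aat_local).max() < 1e-10

    def test_rigid_rotation_rotates_tensors(self, static_system, rng):
        """Directly rotated tensor oracle: P(t) = R P_ref Rᵀ per atom."""
        traj, ref, spec = static_system
        rots = Rotation.random(6, random_state=rng).as_matrix()
        pos = np.einsum("fxy,ay->fax", rots, ref.geometry)
        rot_traj = Trajectory(positions=pos, dt=1.0, elements=traj.elements)
        ts = evolve_tensors_global(rot_traj, [ref], spec)
        expect = np.einsum("fxy,iyz,fwz->fixw", rots, ref.apt, rots)
        assert np.abs(ts.apt - expect).max() < 1e-10

    def test_midway_frame_averages_two_references(self, rng):
        elements = ["C", "O", "H"]
        g1 = np.array([[0.0, 0, 0], [2.0, 0, 0], [0, 2.0, 0]])
        g2 = np.array([[0.0, 0, 0], [2.4, 0, 0], [0, 2.0, 0]])
        mid = 0.5 * (g1 + g2)
        r1, r2 = _ref_from(rng, g1, elements, "a"), _ref_from(rng, g2, elements, "b")
        spec = MetricSpec(
            [MetricFamily(type="interatomic_distance", atoms=[(0, 1)], sigma=0.2)]
        )
        traj = Trajectory(positions=np.tile(mid, (5, 1, 1)), dt=1.0, elements=elements)
        ts = evolve_tensors_global(traj, [r1, r2], spec)
        # symmetric weights: the average of the two (rotated) reference tensors
        from awv.matching import quaternion_fit
        from awv.units import mass_of

        masses = np.array([mass_of(e) for e in elements])
        expect = np.zeros_like(r1.apt)
        for ref in (r1, r2):
            R = quaternion_fit(ref.geometry, mid, masses).rotation
            expect += 0.5 * np.einsum("xy,iyz,wz->ixw", R, ref.apt, R)
        assert np.abs(ts.apt[0] - expect).max() < 1e-9

    def test_atom_count_mismatch_rejected(self, static_system, rng):
        traj, ref, spec = static_system
        small = Trajectory(
            positions=traj.positions[:, :3], dt=1.0, elements=traj.elements[:3]
        )
        with pytest.raises(ValueError, match="atom count"):
            evolve_tensors_global(small, [ref], spec)


class TestEvolveFragments:
    def test_single_fragment_reduces_to_global(self, static_system, rng):
        traj, ref, spec = static_system
        jitter = traj.positions + 0.05 * rng.standard_normal(traj.positions.shape)
        traj = Trajectory(positions=jitter, dt=1.0, elements=traj.elements)
        topo = Topology(molecules=[np.arange(4)])
        frag = FragmentDefinition(
            name="all", atoms=np.arange(4), references=[ref], metric_spec=spec
        )
        ts_f = evolve_tensors_fragments(traj, topo, [[frag]])
        ts_g = evolve_tensors_global(traj, [ref], spec)
        assert np.abs(ts_f.apt - ts_g.apt).max() < 1e-12
        assert np.abs(ts_f.aat_local - ts_g.aat_local).max() < 1e-12

    def test_static_dimer_assembles_block_concatenation(self, rng):
        elements = ["C", "O", "H"]
        geom = rng.standard_normal((3, 3))
        ref = _ref_from(rng, geom, elements)
        spec = MetricSpec(
            [MetricFamily(type="interatomic_distance", atoms=[(0, 1), (1, 2)], sigma=0.5)]
        )
        two = np.concatenate([geom, geom + np.array([6.0, 0, 0])])
        traj = Trajectory(
            positions=np.tile(two, (6, 1, 1)), dt=1.0, elements=elements * 2
        )
        topo = Topology(molecules=[np.arange(3), np.arange(3, 6)])
        frag = FragmentDefinition(
            name="mol", atoms=np.arange(3), references=[ref], metric_spec=spec
        )
        ts = evolve_tensors_fragments(traj, topo, [[frag], [frag]])
        assert np.abs(ts.apt[:, :3] - ref.apt).max() < 1e-10
        assert np.abs(ts.apt[:, 3:] - ref.apt).max() < 1e-10

    def test_overlapping_fragments_rejected(self, static_system):
        traj, ref, spec = static_system
        topo = Topology(molecules=[np.arange(4)])
        f1 = FragmentDefinition("a", np.arange(3), [ref], spec)
        f2 = FragmentDefinition("b", np.arange(1, 4), [ref], spec)
        with pytest.raises(ValueError, match="overlap"):
            evolve_tensors_fragments(traj, topo, [[f1, f2]])

    def test_incomplete_coverage_rejected(self, static_system):
        traj, ref, spec = static_system
        topo = Topology(molecules=[np.arange(4)])
        f1 = FragmentDefinition("a", np.arange(3), [ref], spec)
        with pytest.raises(ValueError, match="cover"):
            evolve_tensors_fragments(traj, topo, [[f1]])

    def test_small_fragment_requires_exemption_flag(self, static_system):
        _, ref, spec = static_system
        with pytest.raises(ValueError, match="allow_small"):
            FragmentDefinition("tiny", [0, 1], [ref], spec)
        FragmentDefinition("tiny", [0, 1], [ref], spec, allow_small=True)


class TestWeightedDerivatives:
    def _series(self, rng, n_frames=20, n_atoms=4):
        elements = ["C", "O", "H", "H"]
        geom = rng.standard_normal((n_atoms, 3)) * 2
        ref = _ref_from(rng, geom, elements)
        pos = geom + 0.05 * rng.standard_normal((n_frames, n_atoms, 3))
        traj = Trajectory(positions=pos, dt=1.0, elements=elements)
        spec = MetricSpec(
            [MetricFamily(type="interatomic_distance", atoms=[(0, 1)], sigma=0.5)]
        )
        ts = evolve_tensors_global(traj, [ref], spec)
        return ts, ref

    def test_identity_apt_zero_aat_sums_velocities(self, rng):
        from awv.reference import GAUGE_PREFACTOR
        from awv.units import BOHR_A

        ts, ref = self._series(rng)
        ts.apt[:] = np.eye(3)
        ts.aat_local[:] = 0.0
        v = rng.standard_normal(ts.positions.shape)
        a = rng.standard_normal(ts.positions.shape)
        topo = Topology(molecules=[np.arange(4)])
        ds = weighted_derivatives(ts, v, a, topo)
        expect = v.sum(axis=1)
        expect -= expect.mean(axis=0)
        assert np.abs(ds.mu_dot[:, 0] - expect).max() < 1e-12
        # zero local AAT leaves only the gauge moment-arm term κ Σ r × a
        arm = GAUGE_PREFACTOR * np.cross(ts.positions / BOHR_A, a).sum(axis=1)
        arm -= arm.mean(axis=0)
        assert np.abs(ds.m_dot[:, 0] - arm).max() < 1e-12

    def test_zero_apt_and_aat_give_zero_m_dot(self, rng):
        ts, _ = self._series(rng)
        ts.apt[:] = 0.0
        ts.aat_local[:] = 0.0
        topo = Topology(molecules=[np.arange(4)])
        ds = weighted_derivatives(
            ts,
            rng.standard_normal(ts.positions.shape),
            rng.standard_normal(ts.positions.shape),
            topo,
        )
        assert np.abs(ds.m_dot).max() == 0.0

    def test_zero_velocities_give_zero_mu_dot(self, rng):
        ts, _ = self._series(rng)
        topo = Topology(molecules=[np.arange(4)])
        ds = weighted_derivatives(
            ts, np.zeros(ts.positions.shape), rng.standard_normal(ts.positions.shape), topo
        )
        assert np.abs(ds.mu_dot).max() == 0.0

    def test_linear_in_reference_tensor_scale(self, rng):
        ts, ref = self._series(rng)
        v = rng.standard_normal(ts.positions.shape)
        a = rng.standard_normal(ts.positions.shape)
        topo = Topology(molecules=[np.arange(4)])
        ds1 = weighted_derivatives(ts, v, a, topo)
        ts.apt *= 3.0
        ts.aat_local *= 3.0
        ds3 = weighted_derivatives(ts, v, a, topo)
        assert np.abs(ds3.mu_dot - 3 * ds1.mu_dot).max() < 1e-12
        # m_dot has an APT-dependent gauge part; both pieces scale linearly
        assert np.abs(ds3.m_dot - 3 * ds1.m_dot).max() < 1e-10

    def test_scalar_correlation_rotationally_covariant(self, model3):
        """Rotating trajectory and lab frame together leaves ⟨μ̇·ṁ⟩ unchanged."""
        from awv.oracle import generate_harmonic_trajectory

        traj = generate_harmonic_trajectory(model3, 500, 0.5, seed=4)
        spec = MetricSpec(
            [MetricFamily(type="interatomic_distance", atoms=[(0, 1)], sigma=0.5)]
        )
        topo = Topology(molecules=[np.arange(4)])

        def corr(t, ref):
            ts = evolve_tensors_global(t, [ref], spec)
            ds = weighted_derivatives(
                ts,
                np.gradient(t.positions, t.dt, axis=0),
                np.gradient(np.gradient(t.positions, t.dt, axis=0), t.dt, axis=0),
                topo,
            )
            return float(np.einsum("fx,fx->", ds.mu_dot[:, 0], ds.m_dot[:, 0]))

        ref = model3.reference_structure()
        Q = Rotation.from_rotvec([0.3, -0.2, 0.8]).as_matrix()
        rot_traj = Trajectory(
            positions=np.einsum("xy,fay->fax", Q, traj.positions),
            dt=traj.dt,
            elements=traj.elements,
            masses=traj.masses,
        )
        rot_ref = ReferenceStructure(
            label="rot",
            geometry=model3.x_eq @ Q.T,
            elements=ref.elements,
            apt=np.einsum("xy,iyz,wz->ixw", Q, model3.apt, Q),
            aat_local=np.einsum("xy,iyz,wz->ixw", Q, model3.aat_local, Q),
        )
        c0 = corr(traj, ref)
        c1 = corr(rot_traj, rot_ref)
        assert c1 == pytest.approx(c0, rel=1e-8)

    def test_mu_dot_matches_analytic_time_derivative(self, model3):
        """Constant-tensor harmonic system: μ̇ = P·v with exact velocities
        equals d/dt of P·(x − x_eq) computed analytically."""
        from awv.oracle import generate_harmonic_trajectory
        from awv.trajectory import finite_difference_derivatives

        traj = generate_harmonic_trajectory(model3, 3000, 0.5, seed=9)
        dv = finite_difference_derivatives(traj)
        spec = MetricSpec(
            [MetricFamily(type="interatomic_distance", atoms=[(0, 1)], sigma=0.5)]
        )
        ts = evolve_tensors_global(
            traj, [model3.reference_structure()], spec, frames=dv.frames
        )
        topo = Topology(molecules=[np.arange(4)])
        ds = weighted_derivatives(ts, dv.velocities, dv.accelerations, topo)
        mu_exact = np.einsum("iuw,fiw->fu", model3.apt, traj.velocities[dv.frames])
        mu_exact -= mu_exact.mean(axis=0)
        # evolved tensors wiggle slightly (fit follows the vibration); compare loosely
        scale = np.abs(mu_exact).max()
        assert np.abs(ds.mu_dot[:, 0] - mu_exact).max() < 0.05 * scale
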