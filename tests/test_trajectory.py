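"""Trajectory I/O, finite differences, rotation removal, PBC wrapping."""

import numpy as np
import pytest

from awv.trajectory import (
    Topology,
    Trajectory,
    finite_difference_derivatives,
    five_point_derivative,
    read_xyz_trajectory,
    remove_global_rotation,
    wrap_molecules,
    write_xyz_trajectory,
)
from awv.units import KB_AMU_A2_FS2


def _toy_traj(n_frames=10, n_atoms=3, dt=0.5, seed=0, **kw):
    rng = np.random.default_rng(seed)
    return Trajectory(
        positions=rng.standard_normal((n_frames, n_atoms, 3)),
        dt=dt,
        elements=["C", "O", "H"][:n_atoms],
        **kw,
    )


class TestXYZRoundTrip:
    def test_positions_velocities_box_survive(self, tmp_path):
        traj = _toy_traj(n_frames=100, velocities=np.zeros((100, 3, 3)) + 0.25,
                         box=np.array([10.0, 12.0, 14.0]))
        path = tmp_path / "t.xyz"
        write_xyz_trajectory(path, traj)
        back = read_xyz_trajectory(path, dt=traj.dt)
        assert np.abs(back.positions - traj.positions).max() < 1e-6
        assert np.abs(back.velocities - traj.velocities).max() < 1e-6
        assert np.allclose(back.box, traj.box)
        assert back.elements == traj.elements
        # element symbols resolve to standard masses
        assert back.masses[0] == pytest.approx(12.011)

    def test_too_few_frames_rejected(self, tmp_path):
        traj = _toy_traj(n_frames=10)
        path = tmp_path / "t.xyz"
        write_xyz_trajectory(path, traj)
        three = "\n".join(path.read_text().splitlines()[: 3 * (traj.n_atoms + 2)])
        path.write_text(three + "\n")
        with pytest.raises(ValueError, match="at least 5"):
            read_xyz_trajectory(path, dt=0.5)

    def test_inconsistent_atom_count_rejected(self, tmp_path):
        path = tmp_path / "bad.xyz"
        frame1 = "2\nc\nC 0 0 0\nH 1 0 0\n"
        frame2 = "3\nc\nC 0 0 0\nH 1 0 0\nH 0 1 0\n"
        path.write_text(frame1 + frame2 + frame1 * 4)
        with pytest.raises(ValueError, match="inconsistent"):
            read_xyz_trajectory(path, dt=0.5)

    def test_repeated_geometry_reads_as_static(self, tmp_path):
        pos = np.tile(np.arange(9.0).reshape(1, 3, 3), (6, 1, 1))
        traj = Trajectory(positions=pos, dt=1.0, elements=["C", "O", "H"])
        path = tmp_path / "static.xyz"
        write_xyz_trajectory(path, traj)
        back = read_xyz_trajectory(path, dt=1.0)
        assert np.abs(np.diff(back.positions, axis=0)).max() == 0.0


class TestFivePoint:
    @pytest.mark.parametrize("degree", [0, 1, 2, 3, 4])
    def test_exact_on_low_order_polynomials(self, degree):
        dt = 0.3
        t = np.arange(40) * dt
        coeffs = np.arange(1.0, degree + 2)
        y = np.polynomial.polynomial.polyval(t, coeffs)
        dy = np.polynomial.polynomial.polyval(
            t, np.polynomial.polynomial.polyder(coeffs)
        )
        got = five_point_derivative(y, dt)
        scale = max(np.abs(dy).max(), 1.0)
        assert np.abs(got - dy[2:-2]).max() / scale < 1e-10

    def test_dt4_error_scaling_on_sine(self):
        w = 0.4
        errs = []
        dts = [0.2, 0.1, 0.05]
        for dt in dts:
            t = np.arange(0, 200, dt)
            v = five_point_derivative(np.sin(w * t), dt)
            errs.append(np.abs(v - w * np.cos(w * t)[2:-2]).max())
        slope = np.polyfit(np.log(dts), np.log(errs), 1)[0]
        assert 3.8 < slope < 4.2

    def test_linear_drift_has_zero_acceleration(self):
        t = np.arange(30) * 0.5
        x = np.outer(t, np.ones(6)).reshape(30, 2, 3) * 1.7
        traj = Trajectory(positions=x, dt=0.5, elements=["H", "H"])
        dv = finite_difference_derivatives(traj)
        assert np.abs(dv.accelerations).max() < 1e-12
        assert np.abs(dv.velocities - 1.7).max() < 1e-12

    def test_constant_positions_give_zero_derivatives(self):
        traj = Trajectory(
            positions=np.ones((12, 2, 3)), dt=0.5, elements=["H", "H"]
        )
        dv = finite_difference_derivatives(traj)
        assert np.abs(dv.velocities).max() == 0.0
        assert np.abs(dv.accelerations).max() == 0.0

    def test_file_velocities_take_precedence(self):
        rng = np.random.default_rng(3)
        pos = rng.standard_normal((12, 2, 3))
        vel = np.tile(np.array([[1.0, 0, 0], [0, 1.0, 0]]), (12, 1, 1))
        traj = Trajectory(positions=pos, dt=0.5, elements=["H", "H"], velocities=vel)
        dv = finite_difference_derivatives(traj)
        assert np.allclose(dv.velocities, vel[2:-2])
        assert np.abs(dv.accelerations).max() < 1e-12  # constant v

    def test_kinetic_energy_matches_equipartition(self, model3, short_harmonic_traj):
        """Derived velocities reproduce the analytic kinetic energy: the
        time-averaged kinetic energy per mode is k_B·T/2."""
        traj = Trajectory(
            positions=short_harmonic_traj.positions,
            dt=short_harmonic_traj.dt,
            elements=short_harmonic_traj.elements,
            masses=short_harmonic_traj.masses,
        )
        dv = finite_difference_derivatives(traj)
        ke = 0.5 * np.einsum(
            "a,fax,fax->", traj.masses, dv.velocities, dv.velocities
        ) / len(dv.velocities)
        expected = len(model3.frequencies) * 0.5 * KB_AMU_A2_FS2 * model3.temperature
        assert ke == pytest.approx(expected, rel=0.02)


class TestRemoveGlobalRotation:
    @staticmethod
    def _rigid_rotating_traj(n=30):
        rng = np.random.default_rng(5)
        base = rng.standard_normal((4, 3))
        from scipy.spatial.transform import Rotation

        pos = np.array(
            [Rotation.from_rotvec([0, 0, 0.1 * i]).apply(base) for i in range(n)]
        )
        return Trajectory(positions=pos, dt=1.0, elements=["C", "O", "H", "H"])

    def test_rigid_rotation_removed_completely(self):
        traj = self._rigid_rotating_traj()
        out = remove_global_rotation(traj)
        assert np.abs(np.diff(out.positions, axis=0)).max() < 1e-8

    def test_identity_on_aligned_trajectory(self):
        traj = _toy_traj(n_frames=8)
        static = Trajectory(
            positions=np.tile(traj.positions[0], (8, 1, 1)),
            dt=1.0,
            elements=traj.elements,
        )
        out = remove_global_rotation(static)
        assert np.abs(out.positions - static.positions).max() < 1e-10

    def test_idempotent(self):
        traj = self._rigid_rotating_traj()
        once = remove_global_rotation(traj)
        twice = remove_global_rotation(once)
        assert np.abs(twice.positions - once.positions).max() < 1e-10

    @pytest.mark.parametrize(
        ("temperature", "rate", "bound"),
        [
            # the quaternion fit satisfies the Eckart conditions to first
            # order in the displacement: the residual scales with T (∝ A²)
            (300.0, 0.002, 1e-2),
            (1.0, 0.02, 1e-6),  # small-amplitude limit
        ],
    )
    def test_angular_momentum_suppressed(self, temperature, rate, bound):
        """Vibration + superimposed rigid rotation: after removal the total
        angular momentum about the center of mass is strongly suppressed,
        vanishing in the small-amplitude (Eckart) limit."""
        from scipy.spatial.transform import Rotation

        from awv.oracle import generate_harmonic_trajectory, random_harmonic_model

        model = random_harmonic_model(
            4, [800.0, 1200.0, 1600.0], seed=7, temperature=temperature
        )
        traj = generate_harmonic_trajectory(model, 2000, 0.5, seed=2)
        rots = [
            Rotation.from_rotvec([0, rate * i, 2 * rate * i]) for i in range(2000)
        ]
        pos = np.array([r.apply(p) for r, p in zip(rots, traj.positions)])
        spun = Trajectory(positions=pos, dt=0.5, elements=traj.elements,
                          masses=traj.masses)

        def ang_mom(t):
            dv = finite_difference_derivatives(t)
            p = t.positions[dv.frames]
            com = np.einsum("a,fax->fx", t.masses, p) / t.masses.sum()
            rel = p - com[:, None]
            L = np.einsum("a,fax->fx", t.masses, np.cross(rel, dv.velocities))
            return np.linalg.norm(L, axis=1).mean()

        before = ang_mom(spun)
        after = ang_mom(remove_global_rotation(spun))
        assert after < bound * before


class TestWrapMolecules:
    def test_straddling_molecule_made_whole(self):
        box = np.array([10.0, 10.0, 10.0])
        pos = np.array([[[9.8, 5, 5], [0.3, 5, 5], [9.9, 5.5, 5]]] * 6)
        traj = Trajectory(positions=pos, dt=1.0, elements=["C", "H", "H"], box=box)
        topo = Topology(molecules=[np.array([0, 1, 2])])
        out = wrap_molecules(traj, topo)
        d = np.linalg.norm(
            out.positions[:, :, None, :] - out.positions[:, None, :, :], axis=-1
        )
        assert d.max() < box[0] / 2

    def test_identity_without_crossing(self):
        traj = _toy_traj(box=np.array([50.0, 50.0, 50.0]))
        topo = Topology(molecules=[np.array([0, 1, 2])])
        out = wrap_molecules(traj, topo)
        assert np.abs(out.positions - traj.positions).max() == 0.0

    def test_translated_images_share_internal_coordinates(self):
        rng = np.random.default_rng(8)
        box = np.array([12.0, 12.0, 12.0])
        mol = rng.uniform(0, 2, (3, 3))
        shifts = rng.integers(-3, 4, (4, 3)) * box + rng.uniform(0, 10, (4, 3))
        pos = np.concatenate([(mol + s) % box for s in shifts])[None]
        pos = np.tile(pos, (6, 1, 1))
        traj = Trajectory(
            positions=pos, dt=1.0, elements=["C", "O", "H"] * 4, box=box
        )
        topo = Topology(molecules=[np.arange(3) + 3 * i for i in range(4)])
        out = wrap_molecules(traj, topo)
        ref_d = None
        for i in range(4):
            m = out.positions[0, 3 * i : 3 * i + 3]
            d = np.sort(
                np.linalg.norm(m[:, None] - m[None, :], axis=-1).ravel()
            )
            if ref_d is None:
                ref_d = d
            assert np.abs(d - ref_d).max() < 1e-9

    def test_requires_box(self):
        traj = _toy_traj()
        with pytest.raises(ValueError, match="box"):
            wrap_molecules(traj, Topology(molecules=[np.arange(3)]))
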