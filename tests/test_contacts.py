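"""Contact stability, buried SASA, RDF and RMSF."""

import numpy as np
import pytest

from nanopep.core import (AtomSet, AtomTrajectory, DegenerateInputError,
                          EmptyInputError, GeometryError, RangeError)
from nanopep.contacts import (buried_contact_area, contact_stability, rdf,
                              rmsf, sasa)
from nanopep.synthetic_data import synth_hydration_shell


def _toy_traj(pep_z_by_frame, surf_n=12):
    """One-residue peptide (3 atoms) above a small static carbon slab."""
    surf = np.column_stack([np.tile(np.arange(4) * 1.5, 3),
                            np.repeat(np.arange(3) * 1.5, 4),
                            np.zeros(12)])
    frames = []
    for z in pep_z_by_frame:
        pep = np.array([[2.0, 2.0, z], [3.0, 2.0, z], [2.5, 2.8, z]])
        frames.append(np.vstack([pep, surf]))
    elements = np.array(["C"] * 3 + ["C"] * surf_n, dtype=object)
    labels = np.array(["ALA1"] * 3 + ["NANO"] * surf_n, dtype=object)
    template = AtomSet(elements=elements, coords=frames[0],
                       group_labels=labels)
    return AtomTrajectory(template, np.array(frames))


class TestContactStability:
    def test_always_in_contact(self):
        table = contact_stability(_toy_traj([3.0] * 5))
        assert table["ALA1"] == 100.0

    def test_never_in_contact(self):
        table = contact_stability(_toy_traj([10.0] * 5))
        assert table["ALA1"] == 0.0

    def test_partial_contact_counting(self):
        # 7 of 10 frames within the cutoff
        zs = [3.0] * 7 + [10.0] * 3
        table = contact_stability(_toy_traj(zs))
        assert table["ALA1"] == pytest.approx(70.0)

    def test_monotone_in_cutoff(self):
        zs = [3.0, 4.5, 6.0, 9.0]
        traj = _toy_traj(zs)
        vals = [contact_stability(traj, cutoff=c)["ALA1"]
                for c in (2.0, 4.0, 5.0, 7.0, 12.0)]
        assert vals == sorted(vals)

    def test_strict_inequality_at_cutoff(self):
        # distance exactly 4.0 is not a contact ("less than 4 A")
        table = contact_stability(_toy_traj([4.0]))
        assert table["ALA1"] == 0.0

    def test_empty_trajectory_raises(self):
        traj = _toy_traj([3.0])
        empty = AtomTrajectory(traj.template,
                               np.empty((0, traj.n_atoms, 3)))
        with pytest.raises(EmptyInputError):
            contact_stability(empty)


def _carbon_set(coords):
    n = len(coords)
    return AtomSet(elements=np.full(n, "C", dtype=object),
                   coords=np.asarray(coords, dtype=float))


class TestBuriedContactArea:
    def test_zero_at_large_separation(self):
        a = _carbon_set([[0, 0, 0], [1.5, 0, 0]])
        b = _carbon_set([[50, 0, 0], [51.5, 0, 0]])
        assert abs(buried_contact_area(a, b)) <= 0.5

    def test_point_count_self_convergence(self):
        a = _carbon_set([[0, 0, 0], [1.5, 0, 0], [0.7, 1.2, 0]])
        b = _carbon_set([[0.7, 0.5, 3.4], [2.0, 0.5, 3.4]])
        v1 = buried_contact_area(a, b, n_points=960)
        v2 = buried_contact_area(a, b, n_points=1920)
        assert v1 > 5.0  # genuinely buried interface
        assert abs(v2 - v1) / v2 < 0.01

    def test_symmetric_in_argument_order(self):
        a = _carbon_set([[0, 0, 0]])
        b = _carbon_set([[3.3, 0, 0]])
        assert buried_contact_area(a, b) == pytest.approx(
            buried_contact_area(b, a), abs=1e-9)

    def test_coincident_atoms_raise(self):
        a = _carbon_set([[0, 0, 0]])
        b = _carbon_set([[0, 0, 0]])
        with pytest.raises(GeometryError):
            buried_contact_area(a, b)

    def test_sasa_against_mdtraj(self):
        """Cross-check the sphere-point SASA on an all-carbon cluster
        against mdtraj's Shrake-Rupley (same radii for carbon)."""
        mdtraj = pytest.importorskip("mdtraj")
        coords = np.array([[0, 0, 0], [1.5, 0, 0], [0.7, 1.3, 0],
                           [0.7, 0.4, 1.4]], dtype=float)
        atoms = _carbon_set(coords)
        mine = sasa(atoms, probe=1.4, n_points=960)
        top = mdtraj.Topology()
        chain = top.add_chain()
        res = top.add_residue("LIG", chain)
        for i in range(len(coords)):
            top.add_atom(f"C{i}", mdtraj.element.carbon, res)
        traj = mdtraj.Trajectory(coords[None] / 10.0, top)  # nm
        ref = mdtraj.shrake_rupley(traj, probe_radius=0.14,
                                   n_sphere_points=960).sum() * 100.0  # A^2
        assert mine == pytest.approx(ref, rel=0.02)


class TestRdf:
    def _traj_from_points(self, a_coords, b_coords, box):
        coords = np.vstack([a_coords, b_coords])
        n_a, n_b = len(a_coords), len(b_coords)
        atoms = AtomSet(
            elements=np.array(["C"] * n_a + ["O"] * n_b, dtype=object),
            coords=coords,
            group_labels=np.array(["SOL1"] * n_a + ["WAT2"] * n_b,
                                  dtype=object),
            cell=np.diag(box), pbc=[True, True, True])
        return (AtomTrajectory(atoms, coords[None]),
                np.arange(n_a), n_a + np.arange(n_b))

    def test_ideal_gas_is_unity(self, rng):
        box = (25.0, 25.0, 25.0)
        a = rng.uniform(0, 25, size=(200, 3))
        b = rng.uniform(0, 25, size=(10000, 3))
        traj, ia, ib = self._traj_from_points(a, b, box)
        r, g = rdf(traj, ia, ib, r_max=10.0, bin_width=0.5)
        mask = r >= 3.0
        assert np.all(np.abs(g[mask] - 1.0) < 0.05)

    def test_delta_shell_single_bin(self):
        box = (30.0, 30.0, 30.0)
        a = np.array([[15.0, 15.0, 15.0]])
        dirs = np.random.default_rng(1).normal(size=(200, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        b = a + 2.0 * dirs
        traj, ia, ib = self._traj_from_points(a, b, box)
        # bin width chosen so the 2.0 A shell falls inside a bin, not on an edge
        r, g = rdf(traj, ia, ib, r_max=6.0, bin_width=0.3)
        assert r[np.argmax(g)] == pytest.approx(2.0, abs=0.3)
        assert np.count_nonzero(g) == 1

    def test_hydration_shell_peak(self):
        solute = AtomSet(elements=np.array(["C"], dtype=object),
                         coords=np.array([[15.0, 15.0, 15.0]]))
        waters = synth_hydration_shell(solute, shell_radius=2.0,
                                       shell_sigma=0.2, n=20000,
                                       box=(30, 30, 30), seed=4)
        coords = np.vstack([solute.coords, waters.coords])
        atoms = AtomSet(
            elements=np.concatenate([solute.elements, waters.elements]),
            coords=coords,
            group_labels=np.array(["SOL1"] + ["WAT2"] * len(waters),
                                  dtype=object),
            cell=waters.cell, pbc=waters.pbc)
        traj = AtomTrajectory(atoms, coords[None])
        r, g = rdf(traj, [0], 1 + np.arange(len(waters)), r_max=8.0,
                   bin_width=0.1)
        assert r[np.argmax(g)] == pytest.approx(2.0, abs=0.1)

    def test_total_pair_count_preserved(self, rng):
        box = (20.0, 20.0, 20.0)
        a = rng.uniform(0, 20, size=(30, 3))
        b = rng.uniform(0, 20, size=(300, 3))
        traj, ia, ib = self._traj_from_points(a, b, box)
        r_max, bw = 9.0, 0.3
        r, g = rdf(traj, ia, ib, r_max=r_max, bin_width=bw)
        edges = np.arange(0.0, r_max + bw, bw)[:len(r) + 1]
        shells = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        recovered = (g * shells).sum() * len(ib) / np.prod(box) * len(ia)
        tpl = traj.template
        d = tpl.minimum_image(traj.coords[0][ia][:, None]
                              - traj.coords[0][ib][None])
        direct = int((np.linalg.norm(d, axis=-1) < r_max).sum())
        assert recovered == pytest.approx(direct, rel=0.01)

    def test_r_max_beyond_half_box_raises(self, rng):
        traj, ia, ib = self._traj_from_points(
            rng.uniform(0, 10, (5, 3)), rng.uniform(0, 10, (5, 3)),
            (10.0, 10.0, 10.0))
        with pytest.raises(RangeError):
            rdf(traj, ia, ib, r_max=6.0)


class TestRmsf:
    def _traj(self, frames, labels):
        template = AtomSet(
            elements=np.full(frames.shape[1], "C", dtype=object),
            coords=frames[0],
            group_labels=np.asarray(labels, dtype=object))
        return AtomTrajectory(template, frames)

    def test_static_trajectory_is_zero(self):
        base = np.random.default_rng(0).uniform(0, 10, size=(6, 3))
        traj = self._traj(np.repeat(base[None], 4, axis=0),
                          ["ALA1"] * 3 + ["GLY2"] * 3)
        for v in rmsf(traj).values():
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_oscillating_atom_closed_form(self):
        """One atom oscillating +-1 A; oracle applies the same pipeline
        with scipy's independent Kabsch (align_vectors)."""
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(3)
        base = rng.uniform(0, 8, size=(8, 3))
        frames = np.repeat(base[None], 6, axis=0)
        frames[:, 0, 0] += np.array([1.0, -1.0] * 3)
        labels = ["ALA1"] * 4 + ["GLY2"] * 4
        traj = self._traj(frames, labels)
        result = rmsf(traj)

        # independent recomputation
        ref = frames[0] - frames[0].mean(axis=0)
        aligned = []
        for f in frames:
            fc = f - f.mean(axis=0)
            rot, _ = Rotation.align_vectors(ref, fc)
            aligned.append(fc @ rot.as_matrix().T)
        aligned = np.asarray(aligned)
        msf = ((aligned - aligned.mean(axis=0)) ** 2).sum(-1).mean(0)
        assert result["ALA1"] == pytest.approx(float(np.sqrt(msf[:4].mean())),
                                               abs=1e-9)
        assert result["GLY2"] == pytest.approx(float(np.sqrt(msf[4:].mean())),
                                               abs=1e-9)
        # the moving atom dominates: residue RMSF ~ amplitude/sqrt(n_atoms)
        assert result["ALA1"] == pytest.approx(1.0 / np.sqrt(4), rel=0.15)

    def test_global_rotation_removed(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(9)
        base = rng.uniform(0, 8, size=(5, 3))
        frames = []
        for i in range(5):
            rot = Rotation.random(random_state=np.random.RandomState(i))
            frames.append(base @ rot.as_matrix().T + i * 2.0)
        traj = self._traj(np.asarray(frames), ["ALA1"] * 5)
        assert rmsf(traj)["ALA1"] == pytest.approx(0.0, abs=1e-9)

    def test_single_frame_raises(self):
        base = np.zeros((3, 3))
        traj = self._traj(base[None], ["ALA1"] * 3)
        with pytest.raises(DegenerateInputError):
            rmsf(traj)
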