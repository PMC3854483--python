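"""Pi-stacking classification, arrangement categories, occupancy."""

import itertools

import numpy as np
import pytest

from nanopep.core import EmptyInputError, SelectionError
from nanopep.stacking import (StackState, StackingParams, categorize_pair,
                              classify_ring, occupancy, track_trajectory,
                              tracking_map)
from nanopep.synthetic_data import (PoseSpec, _brute_classify, place_ring,
                                    random_pose_specs,
                                    synth_adsorption_trajectory)


def _hexagon_over(graphene, height, shift=0.0, tilt_deg=0.0, cc=1.39):
    """Hand-built probe hexagon over the most central graphene hexagon."""
    hexes = [r for r in graphene.rings if r.size == 6]
    mid = graphene.atoms.coords.mean(axis=0)
    anchor = min(hexes, key=lambda r: np.linalg.norm(r.centroid - mid))
    ang = np.deg2rad(60.0) * np.arange(6)
    pts = np.column_stack([cc * np.cos(ang), cc * np.sin(ang), np.zeros(6)])
    if tilt_deg:
        th = np.deg2rad(tilt_deg)
        rot = np.array([[np.cos(th), 0, np.sin(th)], [0, 1, 0],
                        [-np.sin(th), 0, np.cos(th)]])
        pts = pts @ rot.T
    return pts + anchor.centroid + np.array([shift, 0.0, height])


class TestClassifyRing:
    def test_face_to_face_centered(self, graphene):
        state = classify_ring(_hexagon_over(graphene, 3.4), graphene)
        assert state.value is StackState.FACE_TO_FACE
        assert state.displacement < 0.1

    def test_lateral_shift_gives_offset(self, graphene):
        state = classify_ring(_hexagon_over(graphene, 3.4, shift=1.0), graphene)
        assert state.value is StackState.OFFSET
        assert state.displacement == pytest.approx(1.0, abs=0.05)

    def test_distance_gives_none(self, graphene):
        state = classify_ring(_hexagon_over(graphene, 5.0), graphene)
        assert state.min_pair_distance > 4.5
        assert state.value is StackState.NONE

    def test_tilt_gives_none(self, graphene):
        state = classify_ring(_hexagon_over(graphene, 3.4, tilt_deg=45.0),
                              graphene)
        assert state.tilt == pytest.approx(45.0, abs=1.0)
        assert state.value is StackState.NONE

    def test_boundary_displacement_is_offset(self, graphene):
        # exactly at the threshold: "less than 0.71" is exclusive
        state = classify_ring(_hexagon_over(graphene, 3.4, shift=0.71),
                              graphene)
        assert state.value is StackState.OFFSET

    def test_pentagons_never_partner(self, c60):
        # a ring posed over any c60 site partners with a hexagon
        specs = random_pose_specs(20, seed=5,
                                  states=("FACE_TO_FACE", "OFFSET"))
        for spec in specs:
            atoms, _ = place_ring(c60, spec)
            state = classify_ring(atoms.coords, c60)
            assert c60.rings[state.partner_ring].size == 6

    def test_rigid_motion_invariance(self, c60, rng):
        from scipy.spatial.transform import Rotation

        from nanopep.nanostructures import NanomaterialModel, detect_rings

        atoms, label = place_ring(c60, PoseSpec("OFFSET", 3.4, 1.05, 5.0))
        rot = Rotation.random(random_state=np.random.RandomState(3)).as_matrix()
        shift = rng.uniform(-30, 30, size=3)
        moved_surface = NanomaterialModel(
            kind="fullerene", atoms=c60.atoms.transformed(rot, shift))
        moved_surface.rings = detect_rings(moved_surface.atoms)
        moved_ring = atoms.coords @ rot.T + shift
        assert classify_ring(moved_ring, moved_surface).value.value == label

    def test_monotone_in_thresholds(self, graphene):
        poses = [_hexagon_over(graphene, h, s, t)
                 for h, s, t in [(3.4, 0.0, 0), (3.4, 1.0, 0), (3.4, 0.5, 20),
                                 (4.2, 0.3, 10), (5.0, 0.0, 0)]]
        for pts in poses:
            loose = classify_ring(pts, graphene,
                                  StackingParams(contact_cutoff=6.0))
            tight = classify_ring(pts, graphene,
                                  StackingParams(contact_cutoff=4.5))
            # widening the contact cutoff never destroys a stacked state
            if tight.value is not StackState.NONE:
                assert loose.value is not StackState.NONE
            strict_f2f = classify_ring(
                pts, graphene, StackingParams(f2f_displacement=0.3))
            if strict_f2f.value is StackState.FACE_TO_FACE:
                assert classify_ring(pts, graphene).value is StackState.FACE_TO_FACE

    def test_agrees_with_brute_force_on_random_poses(self, graphene, rng):
        """Exhaustive plain-loop classifier on arbitrary (unmargined) poses."""
        for _ in range(100):
            pts = _hexagon_over(graphene, rng.uniform(2.8, 6.5),
                                rng.uniform(0, 2.5), rng.uniform(0, 60))
            mine = classify_ring(pts, graphene).value.value
            ref = _brute_classify(pts, graphene)
            assert mine == ref


class TestCategories:
    @pytest.mark.parametrize("a,b,expect", [
        ("NONE", "NONE", 1),
        ("OFFSET", "NONE", 2),
        ("OFFSET", "OFFSET", 3),
        ("FACE_TO_FACE", "NONE", 4),
        ("FACE_TO_FACE", "OFFSET", 5),
        ("FACE_TO_FACE", "FACE_TO_FACE", 6),
    ])
    def test_mapping(self, a, b, expect):
        assert categorize_pair(a, b) == expect
        assert categorize_pair(b, a) == expect  # unordered

    def test_nine_ordered_pairs_give_six_categories(self):
        states = list(StackState)
        cats = {categorize_pair(a, b)
                for a, b in itertools.product(states, states)}
        assert cats == set(range(1, 7))


class TestTrajectoryTracking:
    def test_all_face_to_face(self, peptide, graphene):
        spec = PoseSpec("FACE_TO_FACE", height=3.4)
        traj, _ = synth_adsorption_trajectory(
            peptide, graphene, [(spec, spec)] * 10, seed=0)
        records = track_trajectory(traj, graphene, peptide.aromatic_rings)
        assert [r.category for r in records] == [6] * 10

    def test_matches_generator_ground_truth(self, peptide, graphene):
        sched = list(zip(random_pose_specs(12, seed=31),
                         random_pose_specs(12, seed=32)))
        traj, labels = synth_adsorption_trajectory(peptide, graphene, sched,
                                                   seed=33)
        records = track_trajectory(traj, graphene, peptide.aromatic_rings)
        assert [r.category for r in records] == [l["category"] for l in labels]
        assert [r.state_tyr.value.value for r in records] == \
            [l["tyr"] for l in labels]

    def test_empty_trajectory(self, peptide, graphene):
        from nanopep.core import AtomTrajectory

        traj = AtomTrajectory(peptide.atoms,
                              np.empty((0, peptide.atoms.n_atoms, 3)))
        assert track_trajectory(traj, graphene, peptide.aromatic_rings) == []

    def test_bad_selector(self, peptide, graphene):
        from nanopep.core import AtomTrajectory

        traj = AtomTrajectory(peptide.atoms, peptide.atoms.coords[None])
        with pytest.raises(SelectionError):
            track_trajectory(traj, graphene, [[0, 1, 2], peptide.aromatic_rings[1]])


class TestOccupancy:
    def _records(self, peptide, graphene, cats):
        spec = {1: ("NONE", "NONE"), 3: ("OFFSET", "OFFSET"),
                6: ("FACE_TO_FACE", "FACE_TO_FACE")}
        sched = [(PoseSpec(spec[c][0], height=6.0 if c == 1 else 3.4,
                           lateral_shift=1.05 if c == 3 else 0.0),
                  PoseSpec(spec[c][1], height=6.0 if c == 1 else 3.4,
                           lateral_shift=1.05 if c == 3 else 0.0))
                 for c in cats]
        traj, _ = synth_adsorption_trajectory(peptide, graphene, sched, seed=9)
        return track_trajectory(traj, graphene, peptide.aromatic_rings)

    def test_pure_category(self, peptide, graphene):
        recs = self._records(peptide, graphene, [6] * 5)
        table = occupancy(recs)
        assert table.per_category[6] == 100.0
        assert sum(v for c, v in table.per_category.items() if c != 6) == 0.0

    def test_known_mixture_recovered(self, peptide, graphene):
        # 50/30/20 mixture of categories 1/3/6
        recs = self._records(peptide, graphene,
                             [1] * 5 + [3] * 3 + [6] * 2)
        table = occupancy(recs)
        assert table.per_category[1] == pytest.approx(50.0)
        assert table.per_category[3] == pytest.approx(30.0)
        assert table.per_category[6] == pytest.approx(20.0)
        assert table.main_groups["no_stacking"] == pytest.approx(50.0)
        assert table.main_groups["offset"] == pytest.approx(30.0)
        assert table.main_groups["face_to_face"] == pytest.approx(20.0)

    def test_sums_to_100(self, peptide, graphene):
        recs = self._records(peptide, graphene, [1, 3, 6, 6, 3, 1, 1])
        assert sum(occupancy(recs).per_category.values()) == \
            pytest.approx(100.0, abs=1e-9)

    def test_empty_raises(self):
        with pytest.raises(EmptyInputError):
            occupancy([])


class TestTrackingMap:
    def test_counts_match_ground_truth(self, peptide, graphene):
        sched = list(zip(random_pose_specs(10, seed=51),
                         random_pose_specs(10, seed=52)))
        traj, labels = synth_adsorption_trajectory(peptide, graphene, sched,
                                                   seed=53)
        coms, counts = tracking_map(traj, graphene, peptide.aromatic_rings)
        expect = [int(l["tyr"] != "NONE") + int(l["phe"] != "NONE")
                  for l in labels]
        assert counts.tolist() == expect
        assert coms.shape == (10, 3)

    def test_no_contact_counts_zero(self, peptide, graphene):
        spec = PoseSpec("NONE", height=6.0)
        traj, _ = synth_adsorption_trajectory(peptide, graphene,
                                              [(spec, spec)] * 3, seed=1)
        _, counts = tracking_map(traj, graphene, peptide.aromatic_rings)
        assert counts.tolist() == [0, 0, 0]
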