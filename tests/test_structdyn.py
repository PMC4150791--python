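"""Contacts, H-bond occupancy and SASA against brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from satselseq.structdyn import (
    HBondCriteria,
    Trajectory,
    fraction_buried,
    hbond_occupancy,
    min_residue_dna_distance,
    sasa,
    sasa_atoms,
    sphere_points,
    time_averaged_contacts,
    write_multimodel_pdb,
)


def make_traj(frames, elements, residue_index, chain_class, resnames=None, names=None):
    n = len(elements)
    return Trajectory(
        coords=np.asarray(frames, dtype=float),
        elements=np.array(elements),
        atom_names=np.array(names if names is not None else [f"X{i}" for i in range(n)]),
        residue_index=np.array(residue_index),
        resnames=np.array(resnames if resnames is not None else ["ALA"] * n),
        chain_class=np.array(chain_class),
    )


@pytest.fixture
def random_traj():
    """50-atom, 10-frame random system: 30 protein atoms in 6 residues, 20 DNA."""
    rng = np.random.default_rng(12)
    coords = rng.uniform(0, 25, size=(10, 50, 3))
    return make_traj(
        coords,
        elements=["C"] * 30 + ["P"] * 20,
        residue_index=list(np.repeat(np.arange(113, 119), 5)) + list(np.repeat([1, 2], 10)),
        chain_class=["protein"] * 30 + ["dna"] * 20,
        resnames=["LEU"] * 30 + ["DG"] * 10 + ["DC"] * 10,
    )


class TestMinDistance:
    def test_single_atom_residue(self):
        traj = make_traj(
            [[[0, 0, 0], [4, 0, 0], [0, 6, 0]]],
            elements=["C", "P", "P"],
            residue_index=[113, 1, 1],
            chain_class=["protein", "dna", "dna"],
        )
        assert min_residue_dna_distance(traj, 0, 113) == pytest.approx(4.0)

    def test_coincident_atoms_give_zero(self):
        traj = make_traj(
            [[[1, 1, 1], [1, 1, 1]]],
            elements=["C", "P"],
            residue_index=[113, 1],
            chain_class=["protein", "dna"],
        )
        assert min_residue_dna_distance(traj, 0, 113) == 0.0

    def test_matches_exhaustive_pairwise_scan(self, random_traj):
        for frame in range(random_traj.n_frames):
            for residue in range(113, 119):
                res_atoms = random_traj.protein_residue_atoms(residue)
                brute = min(
                    np.linalg.norm(random_traj.coords[frame, i] - random_traj.coords[frame, j])
                    for i in res_atoms
                    for j in random_traj.dna_atoms
                )
                assert min_residue_dna_distance(random_traj, frame, residue) == pytest.approx(brute)

    def test_no_dna_atoms_is_an_error(self):
        traj = make_traj(
            [[[0, 0, 0]]], elements=["C"], residue_index=[113], chain_class=["protein"]
        )
        with pytest.raises(ValueError, match="DNA"):
            min_residue_dna_distance(traj, 0, 113)

    def test_rigid_motion_invariance(self, random_traj):
        rot = Rotation.from_euler("xyz", [20, -35, 110], degrees=True).as_matrix()
        shifted = Trajectory(
            coords=random_traj.coords @ rot.T + np.array([5.0, -3.0, 11.0]),
            elements=random_traj.elements,
            atom_names=random_traj.atom_names,
            residue_index=random_traj.residue_index,
            resnames=random_traj.resnames,
            chain_class=random_traj.chain_class,
        )
        for residue in (113, 116):
            assert min_residue_dna_distance(shifted, 0, residue) == pytest.approx(
                min_residue_dna_distance(random_traj, 0, residue), abs=1e-6
            )


class TestTimeAveragedContacts:
    def _two_frame(self):
        return make_traj(
            [
                [[0, 0, 0], [4, 0, 0]],
                [[0, 0, 0], [6, 0, 0]],
            ],
            elements=["C", "P"],
            residue_index=[113, 1],
            chain_class=["protein", "dna"],
        )

    def test_mean_of_per_frame_minima(self):
        contacts = time_averaged_contacts(self._two_frame(), [113])
        assert contacts.mean[113] == pytest.approx(5.0)
        assert list(contacts.per_frame[113]) == pytest.approx([4.0, 6.0])

    def test_single_frame_equals_min_distance(self):
        traj = self._two_frame()
        contacts = time_averaged_contacts(traj, [113], frames=slice(0, 1))
        assert contacts.mean[113] == pytest.approx(min_residue_dna_distance(traj, 0, 113))

    def test_frame_range_restriction_recomputed_by_hand(self):
        traj = make_traj(
            [[[0, 0, 0], [d, 0, 0]] for d in (2.0, 4.0, 6.0, 8.0)],
            elements=["C", "P"],
            residue_index=[113, 1],
            chain_class=["protein", "dna"],
        )
        assert time_averaged_contacts(traj, [113]).mean[113] == pytest.approx(5.0)
        tail = time_averaged_contacts(traj, [113], frames=slice(2, None))
        assert tail.mean[113] == pytest.approx(7.0)

    def test_concatenation_is_length_weighted_mean(self, random_traj):
        first = time_averaged_contacts(random_traj, [114], frames=slice(0, 4)).mean[114]
        second = time_averaged_contacts(random_traj, [114], frames=slice(4, None)).mean[114]
        full = time_averaged_contacts(random_traj, [114]).mean[114]
        assert full == pytest.approx((4 * first + 6 * second) / 10)

    def test_empty_frame_selection_is_an_error(self, random_traj):
        with pytest.raises(ValueError, match="empty"):
            time_averaged_contacts(random_traj, [113], frames=slice(10, 10))


class TestHBondOccupancy:
    def _traj(self, distances):
        frames = [[[0, 0, 0], [d, 0, 0]] for d in distances]
        return make_traj(
            frames, elements=["N", "O"], residue_index=[113, 1],
            chain_class=["protein", "dna"],
        )

    def test_fraction_of_frames_within_distance(self):
        distances = [3.0] * 30 + [5.0] * 90
        traj = self._traj(distances)
        with pytest.warns(UserWarning):
            occ = hbond_occupancy(traj, donors=[0], acceptors=[1])
        assert occ == pytest.approx(0.25)

    def test_never_within_distance(self):
        with pytest.warns(UserWarning):
            assert hbond_occupancy(self._traj([6.0] * 10), [0], [1]) == 0.0

    def test_threshold_is_closed_and_matches_brute_force(self):
        distances = [3.5, 3.5001, 3.4999, 4.0]
        traj = self._traj(distances)
        with pytest.warns(UserWarning):
            occ = hbond_occupancy(traj, [0], [1])
        brute = np.mean([d <= 3.5 for d in distances])
        assert occ == pytest.approx(brute)
        assert occ == pytest.approx(0.5)

    def test_angle_criterion_filters_bent_geometries(self):
        # donor at origin, hydrogen between, acceptor either linear (180°)
        # or orthogonal to the D-H axis (90°: fails the 140° cutoff)
        frames = [
            [[0, 0, 0], [1.0, 0, 0], [2.9, 0, 0]],       # linear, within distance
            [[0, 0, 0], [1.0, 0, 0], [1.0, 1.8, 0]],     # bent at ~61°
        ]
        traj = make_traj(
            frames, elements=["N", "H", "O"], residue_index=[113, 113, 1],
            chain_class=["protein", "protein", "dna"],
        )
        occ = hbond_occupancy(traj, donors=[0], acceptors=[2], hydrogens={0: [1]})
        assert occ == pytest.approx(0.5)

    def test_occupancy_monotone_in_criteria(self, random_traj):
        donors = [0, 5, 10]
        acceptors = list(random_traj.dna_atoms[:5])
        with pytest.warns(UserWarning):
            occ_tight = hbond_occupancy(random_traj, donors, acceptors, HBondCriteria(3.0))
            occ_mid = hbond_occupancy(random_traj, donors, acceptors, HBondCriteria(6.0))
            occ_loose = hbond_occupancy(random_traj, donors, acceptors, HBondCriteria(12.0))
        assert occ_tight <= occ_mid <= occ_loose


class TestSasa:
    def test_isolated_carbon_matches_analytic_sphere(self):
        area = sasa_atoms(np.array([[0.0, 0.0, 0.0]]), ["C"], n_points=960)[0]
        analytic = 4 * np.pi * (1.7 + 1.4) ** 2
        assert area == pytest.approx(analytic, rel=0.01)

    def test_fully_enclosed_atom_has_no_area(self):
        shell = 2.0 * sphere_points(60)
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        areas = sasa_atoms(coords, ["C"] * len(coords), n_points=960)
        assert areas[0] == pytest.approx(0.0, abs=1e-9)

    def test_two_overlapping_spheres_match_high_resolution_quadrature(self):
        coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        low = sasa_atoms(coords, ["C", "C"], n_points=960).sum()
        high = sasa_atoms(coords, ["C", "C"], n_points=10_000).sum()
        single = 4 * np.pi * (1.7 + 1.4) ** 2
        assert low < 2 * single
        assert low == pytest.approx(high, rel=0.02)

    def test_unknown_element_is_named(self):
        with pytest.raises(KeyError, match="'Xx'"):
            sasa_atoms(np.zeros((1, 3)), ["Xx"])

    def test_rotation_invariance_within_quadrature_tolerance(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 6, size=(12, 3))
        rot = Rotation.from_euler("zyx", [33, 71, -12], degrees=True).as_matrix()
        a = sasa_atoms(coords, ["C"] * 12).sum()
        b = sasa_atoms(coords @ rot.T + 4.2, ["C"] * 12).sum()
        assert b == pytest.approx(a, rel=0.005)

    def test_per_residue_aggregation(self):
        traj = make_traj(
            [[[0, 0, 0], [20, 0, 0], [40, 0, 0]]],
            elements=["C", "C", "C"],
            residue_index=[113, 113, 114],
            chain_class=["protein"] * 3,
        )
        per_res = sasa(traj, 0)
        single = 4 * np.pi * (1.7 + 1.4) ** 2
        assert per_res[113] == pytest.approx(2 * single, rel=0.01)
        assert per_res[114] == pytest.approx(single, rel=0.01)


class TestFractionBuried:
    def test_isolated_residue_against_own_reference_is_exposed(self):
        traj = make_traj(
            [[[0.0, 0.0, 0.0]]], elements=["C"], residue_index=[113],
            chain_class=["protein"], resnames=["ALA"],
        )
        own = sasa_atoms(np.zeros((1, 3)), ["C"])[0]
        assert fraction_buried(traj, 113, reference=own) == pytest.approx(0.0, abs=1e-9)

    def test_enclosed_residue_is_fully_buried(self):
        shell = 2.0 * sphere_points(60)
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        traj = make_traj(
            [coords],
            elements=["C"] * len(coords),
            residue_index=[113] + [200] * len(shell),
            chain_class=["protein"] * len(coords),
            resnames=["ALA"] * len(coords),
        )
        assert fraction_buried(traj, 113, reference=120.0) == pytest.approx(1.0)

    def test_half_occluded_single_atom(self):
        # a dense wall of spheres whose solvent-expanded surface passes
        # through the test atom's centre buries exactly one hemisphere
        wall_y, wall_z = np.meshgrid(np.arange(-10, 10.5, 1.0), np.arange(-10, 10.5, 1.0))
        wall = np.column_stack(
            [np.full(wall_y.size, 1.7 + 1.4), wall_y.ravel(), wall_z.ravel()]
        )
        coords = np.vstack([[0.0, 0.0, 0.0], wall])
        traj = make_traj(
            [coords],
            elements=["C"] * len(coords),
            residue_index=[113] + [300] * len(wall),
            chain_class=["protein"] * len(coords),
            resnames=["ALA"] * len(coords),
        )
        own = sasa_atoms(np.zeros((1, 3)), ["C"])[0]
        assert fraction_buried(traj, 113, reference=own) == pytest.approx(0.5, abs=0.05)

    def test_gxg_reference_requires_known_residue_type(self):
        traj = make_traj(
            [[[0.0, 0.0, 0.0]]], elements=["C"], residue_index=[113],
            chain_class=["protein"], resnames=["XYZ"],
        )
        with pytest.raises(KeyError, match="XYZ"):
            fraction_buried(traj, 113, reference="gxg")


class TestPdbRoundTrip:
    def test_multimodel_pdb_round_trip(self, tmp_path, random_traj):
        path = tmp_path / "traj.pdb"
        write_multimodel_pdb(random_traj, path)
        loaded = Trajectory.from_pdb(path)
        assert loaded.n_frames == random_traj.n_frames
        assert loaded.n_atoms == random_traj.n_atoms
        assert np.allclose(loaded.coords, random_traj.coords, atol=2e-3)
        assert list(loaded.chain_class) == list(random_traj.chain_class)
        # analyses agree on the round-tripped coordinates
        a = time_averaged_contacts(random_traj, [113]).mean[113]
        b = time_averaged_contacts(loaded, [113]).mean[113]
        assert b == pytest.approx(a, abs=5e-3)
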