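"""Minimum-image distances and contact detection against brute-force oracles."""

import numpy as np
import pytest

from _oracles import all_pairs_contacts, brute_force_min_image
from memlens.contacts import (
    ContactParams,
    contact_series,
    find_contacts,
    min_image_distance,
)
from memlens.errors import ConfigurationError, MemlensError
from memlens.synthetic_data import Placement, ToySystemSpec, make_toy_system
from memlens.trajectory_io import Frame, Species


class TestMinImageDistance:
    def test_identical_points(self):
        assert min_image_distance((1, 2, 3), (1, 2, 3), (10, 10, 10)) == 0.0

    def test_wrap_across_one_face(self):
        d = min_image_distance((0.5, 0, 0), (9.5, 0, 0), (10, 10, 10))
        assert d == pytest.approx(1.0)

    def test_matches_27_image_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            box = rng.uniform(5.0, 40.0, size=3)
            a = rng.uniform(0, box)
            b = rng.uniform(0, box)
            assert min_image_distance(a, b, box) == pytest.approx(
                brute_force_min_image(a, b, box), abs=1e-10
            )

    def test_symmetry_and_torus_triangle_inequality(self):
        rng = np.random.default_rng(7)
        box = np.array([12.0, 17.0, 9.0])
        for _ in range(200):
            a, b, c = (rng.uniform(0, box) for _ in range(3))
            dab = min_image_distance(a, b, box)
            assert dab == pytest.approx(min_image_distance(b, a, box))
            assert dab <= (
                min_image_distance(a, c, box)
                + min_image_distance(c, b, box)
                + 1e-9
            )

    def test_bounded_by_half_box_diagonal(self):
        rng = np.random.default_rng(3)
        box = np.array([8.0, 10.0, 6.0])
        half_diag = float(np.linalg.norm(box / 2))
        for _ in range(200):
            d = min_image_distance(rng.uniform(0, box), rng.uniform(0, box), box)
            assert d <= half_diag + 1e-9

    def test_non_finite_rejected(self):
        with pytest.raises(MemlensError):
            min_image_distance((np.nan, 0, 0), (0, 0, 0), (10, 10, 10))


class TestFindContacts:
    def test_strict_threshold_semantics(self, two_atom_system):
        top, frame = two_atom_system((3.4, 0.0, 0.0))
        assert len(find_contacts(frame, top)) == 1
        top, frame = two_atom_system((3.5, 0.0, 0.0))
        assert len(find_contacts(frame, top)) == 0
        top, frame = two_atom_system((3.4999, 0.0, 0.0))
        assert len(find_contacts(frame, top)) == 1

    def test_hydrogen_contributes_no_pair(self, two_atom_system):
        top, frame = two_atom_system(
            (1.0, 0.0, 0.0), lipid_element="H", lipid_name="H4"
        )
        assert len(find_contacts(frame, top)) == 0

    def test_pair_annotation(self, two_atom_system):
        top, frame = two_atom_system((0.0, 0.0, 3.0))
        [pair] = find_contacts(frame, top).pairs
        assert pair.protein_residue == ("A", 1)
        assert pair.species is Species.POPA
        assert pair.lipid_molecule == 1
        assert pair.distance_A == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_cell_list_equals_all_pairs_oracle(self, seed):
        """500 random atoms in a random box: identical pair sets."""
        rng = np.random.default_rng(seed)
        box = rng.uniform(15.0, 40.0, size=3)
        n_prot, n_lip = 250, 250
        prot = rng.uniform(0, box, size=(n_prot, 3))
        lip = rng.uniform(0, box, size=(n_lip, 3))
        top, frame = _random_system(prot, lip, box)
        found = {
            (p.protein_atom, p.lipid_atom - n_prot)
            for p in find_contacts(frame, top).pairs
        }
        assert found == all_pairs_contacts(prot, lip, box, 3.5)

    def test_translation_and_rewrap_invariance(self):
        spec = ToySystemSpec(
            placements=(
                Placement(residue_number=1, n_pairs=2),
                Placement(residue_number=2, lipid_species=Species.PIP2_P5,
                          lipid_index=0, distance_A=3.3),
            ),
            n_frames=1,
        )
        top, frames, _ = make_toy_system(spec, seed=9)
        frame = frames[0]
        ref = {(p.protein_atom, p.lipid_atom) for p in find_contacts(frame, top).pairs}
        assert ref  # sanity: something planted

        rng = np.random.default_rng(1)
        shifted = Frame(
            coordinates=frame.coordinates + rng.uniform(-50, 50, size=3),
            box=frame.box,
        )
        assert ref == {
            (p.protein_atom, p.lipid_atom)
            for p in find_contacts(shifted, top).pairs
        }

        # per-molecule rewrap: integer box shifts applied molecule-wise
        coords = frame.coordinates.copy()
        for mol in top.molecules:
            shift = rng.integers(-2, 3, size=3) * frame.box
            coords[list(mol.atom_indices)] += shift
        rewrapped = Frame(coordinates=coords, box=frame.box)
        assert ref == {
            (p.protein_atom, p.lipid_atom)
            for p in find_contacts(rewrapped, top).pairs
        }

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(17)
        box = np.array([20.0, 20.0, 20.0])
        prot = rng.uniform(0, box, size=(100, 3))
        lip = rng.uniform(0, box, size=(100, 3))
        top, frame = _random_system(prot, lip, box)
        previous = set()
        for threshold in (1.5, 2.5, 3.5, 5.0):
            pairs = {
                (p.protein_atom, p.lipid_atom)
                for p in find_contacts(
                    frame, top, ContactParams(threshold_A=threshold)
                ).pairs
            }
            assert previous <= pairs
            previous = pairs

    def test_missing_box_raises_with_pbc(self, two_atom_system):
        top, frame = two_atom_system((3.0, 0, 0))
        frame_nobox = Frame(coordinates=frame.coordinates, box=None)
        with pytest.raises(ConfigurationError):
            find_contacts(frame_nobox, top)
        assert len(find_contacts(frame_nobox, top, ContactParams(use_pbc=False))) == 1

    def test_threshold_larger_than_half_box_raises(self, two_atom_system):
        top, frame = two_atom_system((3.0, 0, 0), box=(6.0, 20.0, 20.0))
        with pytest.raises(ConfigurationError):
            find_contacts(frame, top)


class TestContactSeries:
    def test_planted_schedule_counts(self, schedule_system, contact_sets):
        _, top, frames, ledger = schedule_system
        series = contact_series(frames, top, residue_range={3}, species="PIP2")
        assert series.tolist() == [1, 1, 1, 1]
        series_all = contact_series(
            frames, top, residue_range=set(range(1, 11)), species=None
        )
        expected = [
            len([c for c in ledger.contacts if c.frame == t])
            for t in range(len(frames))
        ]
        assert series_all.tolist() == expected

    def test_no_contacts_gives_zero_series(self):
        top, frames, _ = make_toy_system(ToySystemSpec(n_frames=3), seed=2)
        series = contact_series(frames, top, residue_range={1, 2}, species="PIP2")
        assert series.tolist() == [0, 0, 0]

    def test_single_frame_three_pairs(self):
        spec = ToySystemSpec(
            n_frames=1, placements=(Placement(residue_number=1, n_pairs=3),)
        )
        top, frames, _ = make_toy_system(spec, seed=0)
        assert contact_series(frames, top, {1}, "PIP2").tolist() == [3]

    def test_domain_split_selector(self, schedule_system):
        _, top, frames, _ = schedule_system
        n_term = contact_series(frames, top, set(range(1, 326)), "PIP2")
        c_term_range = set(range(326, 934))
        assert n_term.sum() > 0
        with pytest.raises(MemlensError):
            contact_series([], top, {1}, "PIP2")
        # no residues beyond 325 exist here, so the C-term series is zero
        assert contact_series(frames, top, c_term_range, "PIP2").sum() == 0

    def test_empty_residue_range_rejected(self, schedule_system):
        _, top, frames, _ = schedule_system
        with pytest.raises(MemlensError):
            contact_series(frames, top, set(), "PIP2")


def _random_system(prot_pos, lip_pos, box):
    """Assemble a Topology/Frame around raw protein & lipid coordinates."""
    from memlens.trajectory_io import AtomRecord, Molecule, Topology

    n_prot, n_lip = len(prot_pos), len(lip_pos)
    atoms = [
        AtomRecord(i, "CA", "C", "ALA", i + 1, "A", True) for i in range(n_prot)
    ] + [
        AtomRecord(n_prot + j, "P", "P", "POPA", 1000 + j, "L", True)
        for j in range(n_lip)
    ]
    molecules = [
        Molecule(0, Species.PROTEIN,
                 tuple(("A", i + 1, "ALA") for i in range(n_prot)),
                 tuple(range(n_prot)))
    ] + [
        Molecule(1 + j, Species.POPA, (("L", 1000 + j, "POPA"),), (n_prot + j,))
        for j in range(n_lip)
    ]
    top = Topology(atoms=atoms, molecules=molecules)
    frame = Frame(
        coordinates=np.vstack([prot_pos, lip_pos]), box=np.asarray(box, float)
    )
    return top, frame
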