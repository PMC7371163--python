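import numpy as np
import pytest

from memlens.contacts import ContactParams, find_contacts
from memlens.synthetic_data import Placement, make_schedule_trajectory
from memlens.trajectory_io import (
    AtomRecord,
    Frame,
    Molecule,
    Species,
    Topology,
)


def contact_sets_of(frames, topology, params=ContactParams()):
    return [
        find_contacts(fr, topology, params, frame_index=i)
        for i, fr in enumerate(frames)
    ]


@pytest.fixture
def contact_sets():
    return contact_sets_of


@pytest.fixture
def two_atom_system():
    """Factory: one protein heavy atom at the origin and one lipid atom at a
    requested position, in a given box.  The minimal instance for probing
    the contact definition itself."""

    def build(
        lipid_pos,
        box=(20.0, 20.0, 20.0),
        lipid_element="P",
        lipid_name="P",
        lipid_species=Species.POPA,
    ):
        atoms = [
            AtomRecord(0, "CA", "C", "ALA", 1, "A", True),
            AtomRecord(
                1,
                lipid_name,
                lipid_element,
                "POPA",
                100,
                "L",
                lipid_element.upper() not in ("H", "D"),
            ),
        ]
        molecules = [
            Molecule(0, Species.PROTEIN, (("A", 1, "ALA"),), (0,)),
            Molecule(1, lipid_species, (("L", 100, "POPA"),), (1,)),
        ]
        topology = Topology(atoms=atoms, molecules=molecules)
        frame = Frame(
            coordinates=np.array([[0.0, 0.0, 0.0], list(lipid_pos)]),
            box=np.asarray(box, dtype=float),
        )
        return topology, frame

    return build


@pytest.fixture
def basic_schedule():
    """A small schedule covering constant binders, a two-partner residue,
    an intermittent binder and a POPA binder."""
    return [
        Placement(residue_number=1, lipid_species=Species.PIP2_P4,
                  lipid_index=0, n_pairs=2, phosphate="P4"),
        Placement(residue_number=2, lipid_species=Species.PIP2_P5,
                  lipid_index=0, n_pairs=1, phosphate="P4"),
        Placement(residue_number=3, lipid_species=Species.PIP2_P4,
                  lipid_index=1, n_pairs=1, frames=(0, 2)),
        Placement(residue_number=3, lipid_species=Species.PIP2_P4,
                  lipid_index=2, n_pairs=1, frames=(1, 3)),
        Placement(residue_number=4, lipid_species=Species.POPA,
                  lipid_index=0, n_pairs=3, phosphate="P1"),
    ]


@pytest.fixture
def schedule_system(basic_schedule):
    topology, frames, ledger = make_schedule_trajectory(
        basic_schedule, n_frames=4, seed=11
    )
    return basic_schedule, topology, frames, ledger
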