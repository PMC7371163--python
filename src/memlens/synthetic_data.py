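"""Synthetic membrane systems with planted, ground-truth contacts.

Real protein-membrane trajectories are huge and rarely deposited, so every
analysis stage here is validated against toy systems whose answers are
known by construction:

* :func:`make_composition` builds asymmetric-bilayer lipid manifests
  (counts per leaflet, 1:1 split of the two PIP2 protonation species,
  144 waters per lipid, ~0.15 M salt).
* :func:`make_toy_system` lays out a simplified protein and lipids in an
  orthorhombic box and realises a list of planted contacts at exact
  distances, each recorded in a :class:`PlantedLedger`.  Everything that
  is not planted is kept at least ``threshold + margin`` away from the
  protein, so the ledger is the complete ground truth.
* :func:`make_schedule_trajectory` turns a per-frame contact schedule into
  a trajectory whose per-residue means, lifetimes, partner counts and
  distinct-lipid summaries equal the schedule arithmetic
  (:func:`schedule_expectations`).

The synthetic lipids are coarse geometric stand-ins (a named headgroup
plus a few tail beads) with CHARMM-style atom names, so species rules and
the PIP2 site map apply unchanged.  No physical realism is claimed: the
contact analysis depends only on names, species and geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import GenerationError, MemlensError
from .site_classification import SiteCategory, _category_of_group
from .trajectory_io import (
    PIP2_SPECIES,
    AtomRecord,
    Frame,
    Molecule,
    Species,
    Topology,
)

__all__ = [
    "LeafletComposition",
    "CompositionManifest",
    "make_composition",
    "Placement",
    "ToySystemSpec",
    "PlantedContact",
    "PlantedLedger",
    "make_toy_system",
    "make_schedule_trajectory",
    "schedule_expectations",
    "DEFAULT_WATERS_PER_LIPID",
]

DEFAULT_WATERS_PER_LIPID = 144
DEFAULT_SALT_MOLARITY = 0.15

# ---------------------------------------------------------------------------
# Compositions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LeafletComposition:
    """Lipid counts for one leaflet."""

    pip2: int
    chol: int
    popc: int
    pope: int
    popa: int
    psm: int

    @property
    def total(self) -> int:
        return self.pip2 + self.chol + self.popc + self.pope + self.popa + self.psm

    @property
    def pip2_p4(self) -> int:
        """4-protonated PIP2 count; the 1:1 split puts the odd molecule here."""
        return (self.pip2 + 1) // 2

    @property
    def pip2_p5(self) -> int:
        return self.pip2 // 2

    def as_dict(self) -> dict[str, int]:
        return {
            "PIP2": self.pip2,
            "CHOL": self.chol,
            "POPC": self.popc,
            "POPE": self.pope,
            "POPA": self.popa,
            "PSM": self.psm,
        }


@dataclass(frozen=True)
class CompositionManifest:
    """Full bilayer manifest: both leaflets, hydration and salt."""

    upper: LeafletComposition
    lower: LeafletComposition
    waters_per_lipid: int = DEFAULT_WATERS_PER_LIPID
    salt_molarity: float = DEFAULT_SALT_MOLARITY

    @property
    def n_lipids(self) -> int:
        return self.upper.total + self.lower.total

    @property
    def n_waters(self) -> int:
        return self.waters_per_lipid * self.n_lipids


# Reference compositions for a 600-lipid leaflet: the PIP2-free outer
# leaflet, and inner leaflets at 10% and 1% PIP2 (PIP2 and POPA matched).
_UPPER_600 = (0, 210, 240, 30, 0, 120)
_LOWER_10_600 = (60, 180, 90, 150, 60, 60)
_LOWER_1_600 = (6, 210, 144, 174, 6, 60)
_COLUMNS = ("pip2", "chol", "popc", "pope", "popa", "psm")


def _apportion(weights: Sequence[float], total: int) -> list[int]:
    """Largest-remainder rounding of non-negative weights to integer counts
    summing exactly to *total*."""
    w = np.asarray(weights, dtype=np.float64)
    if total == 0 or w.sum() == 0:
        out = [0] * len(w)
        if total and len(w):
            out[0] = total
        return out
    exact = w / w.sum() * total
    base = np.floor(exact).astype(int)
    short = total - int(base.sum())
    order = np.argsort(-(exact - base), kind="stable")
    for i in order[:short]:
        base[i] += 1
    return base.tolist()


def _scale_row(row: Sequence[int], leaflet_size: int) -> LeafletComposition:
    counts = _apportion(row, leaflet_size)
    return LeafletComposition(**dict(zip(_COLUMNS, counts)))


def make_composition(
    pip2_percent: float,
    leaflet_size: int = 600,
    waters_per_lipid: int = DEFAULT_WATERS_PER_LIPID,
    salt_molarity: float = DEFAULT_SALT_MOLARITY,
) -> CompositionManifest:
    """Bilayer composition for a given inner-leaflet PIP2 percentage.

    ``pip2_percent`` of 10 or 1 reproduces the reference 600-lipid rows
    exactly (scaled for other leaflet sizes).  Other percentages set
    PIP2 = POPA = round(percent% of the leaflet), keep the sphingomyelin
    count, and fill the remainder with cholesterol/POPC/POPE in
    proportions interpolated between the two reference rows, preserving
    the leaflet total.
    """
    if leaflet_size <= 0:
        raise MemlensError("leaflet_size must be positive")
    if not 0 <= pip2_percent <= 100:
        raise MemlensError("pip2_percent must lie in [0, 100]")

    upper = _scale_row(_UPPER_600, leaflet_size)
    if pip2_percent == 10:
        lower = _scale_row(_LOWER_10_600, leaflet_size)
    elif pip2_percent == 1:
        lower = _scale_row(_LOWER_1_600, leaflet_size)
    else:
        pip2 = popa = int(round(leaflet_size * pip2_percent / 100.0))
        psm = int(round(60 * leaflet_size / 600.0))
        remaining = leaflet_size - pip2 - popa - psm
        if remaining < 0:
            raise MemlensError(
                f"pip2_percent {pip2_percent} leaves no room for other lipids"
            )
        w = min(max((pip2_percent - 1.0) / 9.0, 0.0), 1.0)
        props = [
            (1 - w) * a + w * b
            for a, b in zip(_LOWER_1_600[1:4], _LOWER_10_600[1:4])
        ]
        chol, popc, pope = _apportion(props, remaining)
        lower = LeafletComposition(
            pip2=pip2, chol=chol, popc=popc, pope=pope, popa=popa, psm=psm
        )
    return CompositionManifest(
        upper=upper,
        lower=lower,
        waters_per_lipid=waters_per_lipid,
        salt_molarity=salt_molarity,
    )


# ---------------------------------------------------------------------------
# Toy topologies with planted contacts
# ---------------------------------------------------------------------------

# Heavy-atom templates (name, element) for the coarse synthetic molecules.
_PIP2_HEAVY = [
    ("P", "P"), ("O11", "O"), ("O12", "O"), ("O13", "O"), ("O14", "O"),
    ("P4", "P"), ("O4", "O"), ("OP42", "O"), ("OP43", "O"), ("OP44", "O"),
    ("P5", "P"), ("O5", "O"), ("OP52", "O"), ("OP53", "O"), ("OP54", "O"),
    ("C11", "C"), ("C12", "C"), ("C13", "C"), ("C14", "C"), ("C15", "C"),
    ("C16", "C"),
    ("C1", "C"), ("C2", "C"), ("C3", "C"),
    ("C21", "C"), ("C22", "C"), ("C31", "C"), ("C32", "C"),
]

_LIPID_TEMPLATES: dict[str, list[tuple[str, str]]] = {
    # protonation hydrogen sits on the protonated phosphate's hydroxyl oxygen
    "PI24": _PIP2_HEAVY + [("H4", "H")],
    "PI25": _PIP2_HEAVY + [("H5", "H")],
    "POPA": [
        ("P", "P"), ("O11", "O"), ("O12", "O"), ("O13", "O"), ("O14", "O"),
        ("C1", "C"), ("C2", "C"), ("C3", "C"),
        ("C21", "C"), ("C22", "C"), ("C31", "C"), ("C32", "C"),
    ],
    "POPC": [
        ("P", "P"), ("O11", "O"), ("O12", "O"), ("O13", "O"), ("O14", "O"),
        ("N", "N"), ("C12", "C"), ("C1", "C"), ("C2", "C"), ("C3", "C"),
        ("C21", "C"), ("C31", "C"),
    ],
    "POPE": [
        ("P", "P"), ("O11", "O"), ("O12", "O"), ("O13", "O"), ("O14", "O"),
        ("N", "N"), ("C12", "C"), ("C1", "C"), ("C2", "C"), ("C3", "C"),
        ("C21", "C"), ("C31", "C"),
    ],
    "PSM": [
        ("P", "P"), ("O11", "O"), ("O12", "O"), ("O13", "O"), ("O14", "O"),
        ("N", "N"), ("C1", "C"), ("C2", "C"), ("C3", "C"),
        ("C21", "C"), ("C31", "C"),
    ],
    "CHL1": [("O3", "O"), ("C3", "C"), ("C10", "C"), ("C13", "C"), ("C17", "C")],
}

_RESNAME_OF_SPECIES = {
    Species.PIP2_P4: "PI24",
    Species.PIP2_P5: "PI25",
    Species.POPA: "POPA",
    Species.OTHER_LIPID: "POPC",
}

# Atoms usable for planting, per phosphate group.  "OTHER" uses ring/chain
# carbons so non-phosphate binding can be planted too.
_PLANT_GROUPS_PIP2 = {
    "P1": ["P", "O11", "O12", "O13", "O14"],
    "P4": ["P4", "O4", "OP42", "OP43", "OP44"],
    "P5": ["P5", "O5", "OP52", "OP53", "OP54"],
    "OTHER": ["C11", "C12", "C13", "C14", "C15", "C16"],
}

_PROTEIN_ATOMS = [
    ("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"),
    ("CB", "C"), ("CG", "C"), ("CD", "C"), ("NE", "N"),
]

# Layout constants (Å).  Spacings are deliberately generous so that only
# planted pairs can ever fall inside the contact threshold.
_ATOM_DY = 6.0  # spacing of protein atoms within a residue
_RES_DX = 12.0  # spacing of residue anchors
_LIPID_DXY = 8.0  # lipid grid spacing
_JITTER = 0.2  # anchor jitter amplitude


@dataclass(frozen=True)
class Placement:
    """One planted contact: a residue touching a specific lipid molecule.

    ``n_pairs`` atom pairs are realised at ``distance_A`` between distinct
    protein atoms of the residue and distinct lipid atoms drawn from the
    requested ``phosphate`` group (``P1``/``P4``/``P5``/``OTHER``; the
    binding-site category follows from the lipid species).  ``frames``
    limits the contact to specific frame indices (``None`` = every frame).
    ``cross_boundary_axis`` shifts the lipid atoms by one full box length
    along that axis, so the contact exists only under the minimum image.
    """

    residue_number: int
    lipid_species: Species = Species.PIP2_P4
    lipid_index: int = 0
    n_pairs: int = 1
    phosphate: str = "P4"
    distance_A: float = 3.0
    frames: tuple[int, ...] | None = None
    cross_boundary_axis: int | None = None


@dataclass
class ToySystemSpec:
    """Recipe for a toy system.

    ``lower_counts`` / ``upper_counts`` map residue names to molecule
    counts for the interacting (inner) and bystander (outer) leaflet.
    """

    n_protein_residues: int = 10
    n_atoms_per_residue: int = 5
    n_frames: int = 5
    lower_counts: Mapping[str, int] = field(
        default_factory=lambda: {"PI24": 2, "PI25": 2, "POPA": 2, "POPC": 2}
    )
    upper_counts: Mapping[str, int] = field(
        default_factory=lambda: {"POPC": 4, "CHL1": 2}
    )
    placements: Sequence[Placement] = field(default_factory=tuple)
    box: tuple[float, float, float] | None = None  # None = auto-size
    frame_interval_ps: float = 240.0
    threshold_A: float = 3.5
    margin_A: float = 0.5
    chain_id: str = "A"


@dataclass(frozen=True)
class PlantedContact:
    frame: int
    chain: str
    residue_number: int
    protein_atom: int
    lipid_atom: int
    lipid_molecule: int
    species: Species
    site_category: SiteCategory | None
    distance_A: float


@dataclass
class PlantedLedger:
    """Complete ground truth of every planted contact pair."""

    contacts: list[PlantedContact]
    n_frames: int

    def frame_pairs(self, frame: int) -> set[tuple[int, int]]:
        return {
            (c.protein_atom, c.lipid_atom)
            for c in self.contacts
            if c.frame == frame
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_frames": self.n_frames,
            "contacts": [
                {
                    "frame": c.frame,
                    "chain": c.chain,
                    "residue_number": c.residue_number,
                    "protein_atom": c.protein_atom,
                    "lipid_atom": c.lipid_atom,
                    "lipid_molecule": c.lipid_molecule,
                    "species": c.species.value,
                    "site_category": (
                        c.site_category.value if c.site_category else None
                    ),
                    "distance_A": c.distance_A,
                }
                for c in self.contacts
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedLedger":
        payload = json.loads(Path(path).read_text())
        contacts = [
            PlantedContact(
                frame=c["frame"],
                chain=c["chain"],
                residue_number=c["residue_number"],
                protein_atom=c["protein_atom"],
                lipid_atom=c["lipid_atom"],
                lipid_molecule=c["lipid_molecule"],
                species=Species(c["species"]),
                site_category=(
                    SiteCategory(c["site_category"]) if c["site_category"] else None
                ),
                distance_A=c["distance_A"],
            )
            for c in payload["contacts"]
        ]
        return cls(contacts=contacts, n_frames=payload["n_frames"])


def _plant_group_atoms(resname: str, group: str) -> list[str]:
    if resname in ("PI24", "PI25"):
        if group not in _PLANT_GROUPS_PIP2:
            raise GenerationError(f"unknown phosphate group {group!r}")
        return list(_PLANT_GROUPS_PIP2[group])
    names = [n for n, _ in _LIPID_TEMPLATES[resname]]
    if group in ("P1", "P4", "P5"):
        if "P" not in names:
            raise GenerationError(f"{resname} has no phosphate group to plant on")
        return [n for n in ("P", "O11", "O12", "O13", "O14") if n in names]
    return [n for n in names if n.startswith("C")]


def _planted_category(species: Species, group: str) -> SiteCategory | None:
    if species not in PIP2_SPECIES:
        return None
    if group == "OTHER":
        return SiteCategory.OTHER
    return _category_of_group(group, species)


def make_toy_system(
    spec: ToySystemSpec, seed: int = 0
) -> tuple[Topology, list[Frame], PlantedLedger]:
    """Build a toy topology + trajectory realising the planted contacts.

    Geometry: protein residues sit on a sparse mid-plane grid, lipid
    molecules on leaflet grids well above and below, with every
    non-planted protein-lipid atom pair separated by far more than
    ``threshold_A + margin_A``.  Each planted pair is realised at exactly
    its stated distance (coordinates rounded to PDB precision).  The
    construction is deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    n_res = spec.n_protein_residues
    natoms_res = spec.n_atoms_per_residue
    if n_res < 1:
        raise GenerationError("need at least one protein residue")
    if not 1 <= natoms_res <= len(_PROTEIN_ATOMS):
        raise GenerationError(
            f"n_atoms_per_residue must be in 1..{len(_PROTEIN_ATOMS)}"
        )

    placements = list(spec.placements)
    for p in placements:
        if not 0 < p.distance_A < spec.threshold_A:
            raise GenerationError(
                f"planted distance {p.distance_A} must lie in (0, threshold "
                f"{spec.threshold_A})"
            )
        if not 1 <= p.residue_number <= n_res:
            raise GenerationError(
                f"placement residue {p.residue_number} outside 1..{n_res}"
            )
        if p.n_pairs < 1:
            raise GenerationError("n_pairs must be >= 1")

    # ---- layout -----------------------------------------------------------
    n_cols = int(np.ceil(np.sqrt(n_res)))
    n_rows = int(np.ceil(n_res / n_cols))
    row_h = _ATOM_DY * (natoms_res - 1) + 14.0

    lower_total = sum(spec.lower_counts.values())
    upper_total = sum(spec.upper_counts.values())
    lip_cols = max(int(np.ceil(np.sqrt(max(lower_total, upper_total, 1)))), 1)

    need_x = max(n_cols * _RES_DX, lip_cols * _LIPID_DXY) + 16.0
    need_y = max(n_rows * row_h, lip_cols * _LIPID_DXY) + 16.0
    if spec.box is None:
        box = np.array([max(need_x, 40.0), max(need_y, 40.0), 90.0])
    else:
        box = np.asarray(spec.box, dtype=np.float64)
        if np.any(box <= 0):
            raise GenerationError("box lengths must be positive")
        if box[0] < need_x or box[1] < need_y or box[2] < 60.0:
            raise GenerationError(
                f"box {tuple(box)} too small for the requested system "
                f"(needs >= ({need_x:.0f}, {need_y:.0f}, 60))"
            )
    for p in placements:
        if p.distance_A > box.min() / 2:
            raise GenerationError("planted distance exceeds half the box")

    z_protein = box[2] / 2.0
    z_lower, z_upper = 20.0, box[2] - 20.0

    atoms: list[AtomRecord] = []
    molecules: list[Molecule] = []
    base: list[np.ndarray] = []
    chain = spec.chain_id

    # ---- protein ----------------------------------------------------------
    prot_atom_index: dict[tuple[int, int], int] = {}  # (resnum, slot) -> atom idx
    prot_indices: list[int] = []
    for r in range(n_res):
        resnum = r + 1
        col, row = r % n_cols, r // n_cols
        anchor = np.array(
            [8.0 + col * _RES_DX, 8.0 + row * row_h, z_protein]
        )
        for slot in range(natoms_res):
            name, element = _PROTEIN_ATOMS[slot]
            idx = len(atoms)
            atoms.append(
                AtomRecord(
                    atom_index=idx,
                    atom_name=name,
                    element=element,
                    residue_name="ARG",
                    residue_number=resnum,
                    chain_id=chain,
                    is_heavy=True,
                )
            )
            base.append(anchor + np.array([0.0, slot * _ATOM_DY, 0.0]))
            prot_atom_index[(resnum, slot)] = idx
            prot_indices.append(idx)
    molecules.append(
        Molecule(
            molecule_id=0,
            species=Species.PROTEIN,
            residue_keys=tuple((chain, r + 1, "ARG") for r in range(n_res)),
            atom_indices=tuple(prot_indices),
        )
    )

    # ---- lipids -----------------------------------------------------------
    # molecule ids per (species, index-within-species) for the lower leaflet
    lipid_mol_id: dict[tuple[Species, int], int] = {}
    lipid_atom_index: dict[tuple[int, str], int] = {}  # (mol_id, name) -> atom idx
    species_counter: dict[Species, int] = {}
    lipid_resnum = 1000
    grid_slot = 0

    def add_lipid(resname: str, species: Species, z0: float, lower: bool) -> None:
        nonlocal lipid_resnum, grid_slot
        col, row = grid_slot % lip_cols, grid_slot // lip_cols
        grid_slot += 1
        jitter = rng.uniform(-_JITTER, _JITTER, size=2)
        anchor = np.array(
            [6.0 + col * _LIPID_DXY + jitter[0], 6.0 + row * _LIPID_DXY + jitter[1], z0]
        )
        mol_id = len(molecules)
        indices = []
        for k, (name, element) in enumerate(_LIPID_TEMPLATES[resname]):
            idx = len(atoms)
            atoms.append(
                AtomRecord(
                    atom_index=idx,
                    atom_name=name,
                    element=element,
                    residue_name=resname,
                    residue_number=lipid_resnum,
                    chain_id="L" if lower else "U",
                    is_heavy=element != "H",
                )
            )
            # headgroup clustered at the anchor, tail beads trailing away
            # from the protein mid-plane
            dz = -1.0 - 0.35 * k if lower else 1.0 + 0.35 * k
            base.append(anchor + np.array([0.12 * k, 0.0, dz]))
            indices.append(idx)
            lipid_atom_index[(mol_id, name)] = idx
        molecules.append(
            Molecule(
                molecule_id=mol_id,
                species=species,
                residue_keys=((("L" if lower else "U"), lipid_resnum, resname),),
                atom_indices=tuple(indices),
            )
        )
        if lower:
            n = species_counter.get(species, 0)
            lipid_mol_id[(species, n)] = mol_id
            species_counter[species] = n + 1
        lipid_resnum += 1

    from .trajectory_io import DEFAULT_SPECIES_RULES

    for resname, count in spec.lower_counts.items():
        species = DEFAULT_SPECIES_RULES[resname]
        for _ in range(count):
            add_lipid(resname, species, z_lower, lower=True)
    grid_slot = 0
    for resname, count in spec.upper_counts.items():
        species = DEFAULT_SPECIES_RULES[resname]
        for _ in range(count):
            add_lipid(resname, species, z_upper, lower=False)

    base_arr = np.round(np.stack(base), 3)
    topology = Topology(atoms=atoms, molecules=molecules)

    # ---- realise placements ----------------------------------------------
    ledger_contacts: list[PlantedContact] = []
    frames: list[Frame] = []
    for t in range(spec.n_frames):
        coords = base_arr.copy()
        used_prot_slots: dict[int, int] = {}  # resnum -> next free slot
        used_lipid_atoms: dict[int, set[str]] = {}
        for p in placements:
            if p.frames is not None and t not in p.frames:
                continue
            resname = _RESNAME_OF_SPECIES.get(p.lipid_species)
            if resname is None:
                raise GenerationError(
                    f"cannot plant contacts on species {p.lipid_species}"
                )
            key = (p.lipid_species, p.lipid_index)
            if key not in lipid_mol_id:
                raise GenerationError(
                    f"lipid {p.lipid_species} #{p.lipid_index} not in the lower "
                    "leaflet pool"
                )
            mol_id = lipid_mol_id[key]
            group_atoms = _plant_group_atoms(resname, p.phosphate)
            taken = used_lipid_atoms.setdefault(mol_id, set())
            free_atoms = [n for n in group_atoms if n not in taken]
            if len(free_atoms) < p.n_pairs:
                raise GenerationError(
                    f"frame {t}: lipid {resname} #{p.lipid_index} has only "
                    f"{len(free_atoms)} free {p.phosphate} atoms, "
                    f"{p.n_pairs} requested"
                )
            slot0 = used_prot_slots.get(p.residue_number, 0)
            if slot0 + p.n_pairs > natoms_res:
                raise GenerationError(
                    f"frame {t}: residue {p.residue_number} needs "
                    f"{slot0 + p.n_pairs} protein atoms but has {natoms_res}"
                )
            used_prot_slots[p.residue_number] = slot0 + p.n_pairs
            shift = np.zeros(3)
            if p.cross_boundary_axis is not None:
                shift[p.cross_boundary_axis] = box[p.cross_boundary_axis]
            cat = _planted_category(p.lipid_species, p.phosphate)
            for k in range(p.n_pairs):
                pa = prot_atom_index[(p.residue_number, slot0 + k)]
                la = lipid_atom_index[(mol_id, free_atoms[k])]
                taken.add(free_atoms[k])
                coords[la] = coords[pa] + np.array([0.0, 0.0, -p.distance_A]) + shift
                ledger_contacts.append(
                    PlantedContact(
                        frame=t,
                        chain=chain,
                        residue_number=p.residue_number,
                        protein_atom=pa,
                        lipid_atom=la,
                        lipid_molecule=mol_id,
                        species=p.lipid_species,
                        site_category=cat,
                        distance_A=p.distance_A,
                    )
                )
        frames.append(
            Frame(
                coordinates=coords,
                box=box.copy(),
                time_ns=t * spec.frame_interval_ps / 1000.0,
            )
        )

    return topology, frames, PlantedLedger(
        contacts=ledger_contacts, n_frames=spec.n_frames
    )


# ---------------------------------------------------------------------------
# Schedule trajectories
# ---------------------------------------------------------------------------


def make_schedule_trajectory(
    schedule: Sequence[Placement],
    n_frames: int,
    seed: int = 0,
    n_protein_residues: int | None = None,
    extra_lipids: Mapping[Species, int] | None = None,
    **spec_kwargs,
) -> tuple[Topology, list[Frame], PlantedLedger]:
    """Trajectory whose analysis reproduces a contact schedule exactly.

    The protein size and per-species lipid pools are sized from the
    schedule (``extra_lipids`` adds never-contacting molecules of a
    species, e.g. to model 18 active PIP2 out of a pool of 60).
    """
    if n_frames < 1:
        raise GenerationError("n_frames must be >= 1")
    schedule = list(schedule)
    for p in schedule:
        if p.frames is not None and any(f >= n_frames for f in p.frames):
            raise GenerationError("schedule references a frame beyond n_frames")

    n_res = n_protein_residues or max((p.residue_number for p in schedule), default=1)
    pools: dict[Species, int] = {}
    for p in schedule:
        pools[p.lipid_species] = max(
            pools.get(p.lipid_species, 0), p.lipid_index + 1
        )
    for sp, extra in (extra_lipids or {}).items():
        pools[sp] = pools.get(sp, 0) + extra

    lower: dict[str, int] = {}
    for sp, count in pools.items():
        resname = _RESNAME_OF_SPECIES[sp]
        lower[resname] = lower.get(resname, 0) + count
    if not lower:
        lower = {"PI24": 1}

    spec = ToySystemSpec(
        n_protein_residues=n_res,
        n_frames=n_frames,
        lower_counts=lower,
        placements=tuple(schedule),
        **spec_kwargs,
    )
    return make_toy_system(spec, seed=seed)


def schedule_expectations(
    schedule: Sequence[Placement], n_frames: int
) -> dict:
    """Ground-truth statistics implied by a schedule, by direct arithmetic.

    Returns ``per_residue`` (mean pair count, lifetime %, distinct
    partners, per-category contact-instance counts, per-species partner
    sets) and ``per_species`` (distinct interacting molecules and the mean
    per-frame count).  Serves as the independent oracle for the analysis
    chain.
    """
    per_res_frame: dict[int, np.ndarray] = {}
    per_res_partners: dict[int, set] = {}
    per_res_sites: dict[int, dict[str, int]] = {}
    species_frame_mols: dict[Species, list[set]] = {}

    for p in schedule:
        frames = range(n_frames) if p.frames is None else p.frames
        counts = per_res_frame.setdefault(
            p.residue_number, np.zeros(n_frames, dtype=np.int64)
        )
        partners = per_res_partners.setdefault(p.residue_number, set())
        sites = per_res_sites.setdefault(p.residue_number, {})
        mols = species_frame_mols.setdefault(
            p.lipid_species, [set() for _ in range(n_frames)]
        )
        cat = _planted_category(p.lipid_species, p.phosphate)
        for t in frames:
            counts[t] += p.n_pairs
            mols[t].add(p.lipid_index)
        partners.add((p.lipid_species, p.lipid_index))
        if cat is not None:
            sites[cat.value] = sites.get(cat.value, 0) + p.n_pairs * len(
                list(frames)
            )

    per_residue = {}
    for resnum, counts in per_res_frame.items():
        per_residue[resnum] = {
            "mean_contacts": float(counts.mean()),
            "lifetime_percent": 100.0 * float((counts > 0).sum()) / n_frames,
            "n_partners": len(per_res_partners[resnum]),
            "site_counts": per_res_sites[resnum],
            "series": counts,
        }

    per_species = {}
    for sp, frame_sets in species_frame_mols.items():
        distinct = set().union(*frame_sets) if frame_sets else set()
        per_species[sp.value] = {
            "distinct_over_window": len(distinct),
            "mean_per_frame": float(np.mean([len(s) for s in frame_sets])),
        }
    return {"per_residue": per_residue, "per_species": per_species}
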