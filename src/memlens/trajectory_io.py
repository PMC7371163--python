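"""Topology/trajectory reading and writing plus molecular species classification.

The analysis downstream only needs four things from a structure file: atom
identity (name, element, residue, chain), a heavy-atom flag, a grouping of
atoms into molecules, and a species label per molecule (protein, the two
singly-protonated PIP2 forms, POPA, bystander lipid, solvent, ion).  This
module produces that view from standard PDB/DCD files via MDAnalysis and
writes round-trippable PDB + DCD pairs.

Only orthorhombic unit cells are supported: the membrane systems this
package targets are rectangular, and the minimum-image arithmetic in
:mod:`memlens.contacts` assumes independent axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import (
    ClassificationError,
    ConsistencyError,
    FormatError,
    MemlensError,
    UnsupportedBoxError,
)

__all__ = [
    "Species",
    "LIPID_SPECIES",
    "PIP2_SPECIES",
    "AtomRecord",
    "Molecule",
    "Topology",
    "Frame",
    "DEFAULT_SPECIES_RULES",
    "DEFAULT_FRAME_INTERVAL_PS",
    "load_species_rules",
    "read_topology",
    "read_frames",
    "write_system",
]


class Species(str, Enum):
    """Molecular species vocabulary used throughout the analysis."""

    PROTEIN = "PROTEIN"
    PIP2_P4 = "PIP2_P4"  # PI(4,5)P2 singly protonated at the 4-phosphate
    PIP2_P5 = "PIP2_P5"  # PI(4,5)P2 singly protonated at the 5-phosphate
    POPA = "POPA"
    OTHER_LIPID = "OTHER_LIPID"
    SOLVENT = "SOLVENT"
    ION = "ION"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Lipid species that participate in protein-lipid contact counting.
LIPID_SPECIES = frozenset(
    {Species.PIP2_P4, Species.PIP2_P5, Species.POPA, Species.OTHER_LIPID}
)

#: The two protonation forms of PI(4,5)P2.
PIP2_SPECIES = frozenset({Species.PIP2_P4, Species.PIP2_P5})

_STANDARD_AMINO_ACIDS = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS HSD HSE HSP ILE LEU LYS MET "
    "PHE PRO SER THR TRP TYR VAL"
).split()

#: Default residue-name -> species mapping (CHARMM naming conventions).
DEFAULT_SPECIES_RULES: dict[str, Species] = {
    **{aa: Species.PROTEIN for aa in _STANDARD_AMINO_ACIDS},
    "SAPI24": Species.PIP2_P4,
    "SAPI25": Species.PIP2_P5,
    # 4-character aliases that survive the PDB residue-name column
    "PI24": Species.PIP2_P4,
    "PI25": Species.PIP2_P5,
    "POPA": Species.POPA,
    "POPC": Species.OTHER_LIPID,
    "POPE": Species.OTHER_LIPID,
    "PSM": Species.OTHER_LIPID,
    "CHL1": Species.OTHER_LIPID,
    "TIP3": Species.SOLVENT,
    "HOH": Species.SOLVENT,
    "POT": Species.ION,
    "K": Species.ION,
    "CLA": Species.ION,
    "CL": Species.ION,
    "SOD": Species.ION,
    "NA": Species.ION,
}

#: Default interval between saved trajectory frames (picoseconds).
DEFAULT_FRAME_INTERVAL_PS = 240.0


@dataclass(frozen=True)
class AtomRecord:
    """One atom as the analysis sees it."""

    atom_index: int
    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    is_heavy: bool


@dataclass(frozen=True)
class Molecule:
    """A molecule: one protein chain, one lipid, one water, or one ion."""

    molecule_id: int
    species: Species
    residue_keys: tuple[tuple[str, int, str], ...]  # (chain, resnum, resname)
    atom_indices: tuple[int, ...]


@dataclass
class Topology:
    """Ordered atoms plus their grouping into molecules.

    Cached numpy views (`heavy_mask`, `atom_species_code`, ...) back the
    vectorised contact search; they are derived, never mutated.
    """

    atoms: list[AtomRecord]
    molecules: list[Molecule]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @cached_property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    @cached_property
    def atom_names(self) -> np.ndarray:
        return np.array([a.atom_name for a in self.atoms], dtype=object)

    @cached_property
    def atom_species(self) -> np.ndarray:
        """Species of the molecule each atom belongs to (object array)."""
        out = np.empty(self.n_atoms, dtype=object)
        for mol in self.molecules:
            for i in mol.atom_indices:
                out[i] = mol.species
        return out

    @cached_property
    def atom_molecule_id(self) -> np.ndarray:
        out = np.full(self.n_atoms, -1, dtype=np.int64)
        for mol in self.molecules:
            out[list(mol.atom_indices)] = mol.molecule_id
        return out

    @cached_property
    def molecule_by_id(self) -> dict[int, Molecule]:
        return {m.molecule_id: m for m in self.molecules}

    @cached_property
    def atom_residue_key(self) -> list[tuple[str, int]]:
        return [(a.chain_id, a.residue_number) for a in self.atoms]

    def protein_residues(self) -> list[tuple[str, int, str]]:
        """Unique protein residues as (chain, residue_number, residue_name),
        in atom order."""
        seen: dict[tuple[str, int], str] = {}
        for mol in self.molecules:
            if mol.species is not Species.PROTEIN:
                continue
            for chain, resnum, resname in mol.residue_keys:
                seen.setdefault((chain, resnum), resname)
        return [(c, n, r) for (c, n), r in seen.items()]

    def molecules_of_species(self, species: Species) -> list[Molecule]:
        return [m for m in self.molecules if m.species is species]


@dataclass
class Frame:
    """One trajectory frame: coordinates (Å), orthorhombic box (Å), time (ns)."""

    coordinates: np.ndarray
    box: np.ndarray | None
    time_ns: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise MemlensError(
                f"coordinates must be (n_atoms, 3), got {self.coordinates.shape}"
            )
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=np.float64).reshape(3)
            if not np.all(self.box > 0):
                raise MemlensError(f"box lengths must be positive, got {self.box}")
        if self.time_ns < 0:
            raise MemlensError("time_ns must be non-negative")

    @property
    def n_atoms(self) -> int:
        return int(self.coordinates.shape[0])


def load_species_rules(path: str | Path) -> dict[str, Species]:
    """Load a residue-name -> species mapping from a YAML or JSON file.

    The file maps residue names to species names, e.g. ``SAPI24: PIP2_P4``.
    Unknown species names raise :class:`ClassificationError`.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise FormatError(f"species rules file {path} must map names to species")
    rules: dict[str, Species] = {}
    for resname, spname in raw.items():
        try:
            rules[str(resname)] = Species(str(spname))
        except ValueError as exc:
            raise ClassificationError(
                f"unknown species {spname!r} for residue {resname!r}"
            ) from exc
    return rules


def _is_hydrogen(element: str, atom_name: str) -> bool:
    """Element column first; if blank, fall back to the atom-name heuristic
    (leading digits stripped, then a leading H means hydrogen)."""
    el = element.strip()
    if el:
        return el.upper() in ("H", "D")
    name = atom_name.strip().lstrip("0123456789")
    return name[:1].upper() == "H"


def _validate_pdb_lines(path: Path) -> None:
    """Light pre-scan so parse failures name the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
                int(line[22:26])
            except (ValueError, IndexError) as exc:
                raise FormatError(
                    f"{path}: unparseable ATOM/HETATM record at line {lineno}: "
                    f"{line.rstrip()!r}"
                ) from exc


def _check_orthorhombic(dimensions: np.ndarray | None, source: str) -> np.ndarray | None:
    if dimensions is None:
        return None
    dims = np.asarray(dimensions, dtype=np.float64)
    if np.allclose(dims[:3], 0.0):
        return None
    if not np.allclose(dims[3:6], 90.0, atol=1e-3):
        raise UnsupportedBoxError(
            f"{source}: triclinic unit cell (angles {dims[3:6]}) is not supported; "
            "only orthorhombic boxes are"
        )
    return dims[:3].copy()


def read_topology(
    path: str | Path,
    species_rules: Mapping[str, Species] | None = None,
) -> Topology:
    """Read a PDB file into a :class:`Topology`.

    Heavy-atom flags come from the element column when present, otherwise
    from the atom-name heuristic.  Protein atoms are grouped into one
    molecule per chain; lipids, solvent and ions into one molecule per
    (residue name, residue number, chain).  Residue names absent from
    *species_rules* raise :class:`ClassificationError`.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FormatError(f"topology file not found: {path}")
    _validate_pdb_lines(path)
    rules = dict(DEFAULT_SPECIES_RULES if species_rules is None else species_rules)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), topology_format="PDB")

    names = u.atoms.names
    resnames = u.atoms.resnames
    resids = u.atoms.resids
    try:
        chains = u.atoms.chainIDs
    except (AttributeError, mda.exceptions.NoDataError):
        chains = np.array([""] * len(u.atoms), dtype=object)
    try:
        elements = u.atoms.elements
    except (AttributeError, mda.exceptions.NoDataError):
        elements = np.array([""] * len(u.atoms), dtype=object)

    unknown = sorted(
        {str(rn) for rn in resnames if str(rn).strip() not in rules}
    )
    if unknown:
        raise ClassificationError(
            "residue name(s) not covered by species rules: " + ", ".join(unknown)
        )

    atoms: list[AtomRecord] = []
    for i in range(len(u.atoms)):
        element = str(elements[i]).strip()
        name = str(names[i]).strip()
        hydrogen = _is_hydrogen(element, name)
        if not element:
            element = "H" if hydrogen else name.lstrip("0123456789")[:1].upper()
        atoms.append(
            AtomRecord(
                atom_index=i,
                atom_name=name,
                element=element,
                residue_name=str(resnames[i]).strip(),
                residue_number=int(resids[i]),
                chain_id=str(chains[i]).strip(),
                is_heavy=not hydrogen,
            )
        )

    molecules = _group_molecules(atoms, rules)
    return Topology(atoms=atoms, molecules=molecules)


def _group_molecules(
    atoms: Sequence[AtomRecord], rules: Mapping[str, Species]
) -> list[Molecule]:
    """Protein: one molecule per chain.  Everything else: one molecule per
    (resname, resnum, chain).  Molecule ids follow first-atom order."""
    groups: dict[object, dict] = {}
    order: list[object] = []
    for atom in atoms:
        species = rules[atom.residue_name]
        if species is Species.PROTEIN:
            key: object = ("protein-chain", atom.chain_id)
        else:
            key = ("single", atom.residue_name, atom.residue_number, atom.chain_id)
        if key not in groups:
            groups[key] = {"species": species, "atoms": [], "residues": {}}
            order.append(key)
        g = groups[key]
        g["atoms"].append(atom.atom_index)
        g["residues"].setdefault(
            (atom.chain_id, atom.residue_number), atom.residue_name
        )
    molecules = []
    for mol_id, key in enumerate(order):
        g = groups[key]
        residue_keys = tuple(
            (c, n, rname) for (c, n), rname in g["residues"].items()
        )
        molecules.append(
            Molecule(
                molecule_id=mol_id,
                species=g["species"],
                residue_keys=residue_keys,
                atom_indices=tuple(g["atoms"]),
            )
        )
    return molecules


def read_frames(
    path: str | Path,
    topology: Topology,
    frame_interval_ps: float = DEFAULT_FRAME_INTERVAL_PS,
) -> list[Frame]:
    """Read a DCD or (multi-model) PDB trajectory into a list of Frames.

    Frame times are ``index * frame_interval_ps`` (in ns); the file's own
    time header is ignored because CHARMM/NAMD dialects disagree on its
    units.  Box lengths come from the DCD unit-cell record or CRYST1.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"trajectory file not found: {path}")
    suffix = path.suffix.lower()
    header_box = None
    if suffix == ".dcd":
        from MDAnalysis.coordinates.DCD import DCDReader

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reader = DCDReader(str(path))
    elif suffix in (".pdb", ".ent"):
        from MDAnalysis.coordinates.PDB import PDBReader

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reader = PDBReader(str(path))
        # a single CRYST1 before the first MODEL applies to every model
        with open(path) as fh:
            for line in fh:
                if line.startswith("CRYST1"):
                    dims = np.array(
                        [line[6:15], line[15:24], line[24:33],
                         line[33:40], line[40:47], line[47:54]],
                        dtype=np.float64,
                    )
                    header_box = _check_orthorhombic(dims, f"{path} CRYST1")
                    break
                if line.startswith(("MODEL", "ATOM", "HETATM")):
                    break
    else:
        raise FormatError(f"unsupported trajectory format: {path.suffix!r}")

    with reader:
        if reader.n_atoms != topology.n_atoms:
            raise ConsistencyError(
                f"trajectory {path} has {reader.n_atoms} atoms but topology "
                f"has {topology.n_atoms}"
            )
        frames: list[Frame] = []
        for i, ts in enumerate(reader):
            box = _check_orthorhombic(ts.dimensions, f"{path} frame {i}")
            if box is None:
                box = header_box
            frames.append(
                Frame(
                    coordinates=np.array(ts.positions, dtype=np.float64),
                    box=box,
                    time_ns=i * frame_interval_ps / 1000.0,
                )
            )
    return frames


def _build_universe(topology: Topology, n_frames: int):
    import MDAnalysis as mda

    residue_index: dict[tuple[str, int, str], int] = {}
    atom_resindex = np.empty(topology.n_atoms, dtype=np.int64)
    for atom in topology.atoms:
        key = (atom.chain_id, atom.residue_number, atom.residue_name)
        if key not in residue_index:
            residue_index[key] = len(residue_index)
        atom_resindex[atom.atom_index] = residue_index[key]
    n_res = len(residue_index)

    chain_order: dict[str, int] = {}
    res_segindex = np.empty(n_res, dtype=np.int64)
    for (chain, _, _), ridx in residue_index.items():
        if chain not in chain_order:
            chain_order[chain] = len(chain_order)
        res_segindex[ridx] = chain_order[chain]

    u = mda.Universe.empty(
        topology.n_atoms,
        n_residues=n_res,
        n_segments=max(len(chain_order), 1),
        atom_resindex=atom_resindex,
        residue_segindex=res_segindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", [a.atom_name for a in topology.atoms])
    u.add_TopologyAttr("elements", [a.element for a in topology.atoms])
    u.add_TopologyAttr("chainIDs", [a.chain_id or "X" for a in topology.atoms])
    resnames = [""] * n_res
    resids = [0] * n_res
    for (chain, resnum, resname), ridx in residue_index.items():
        resnames[ridx] = resname
        resids[ridx] = resnum
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", resids)
    u.add_TopologyAttr("segids", [c or "X" for c in chain_order] or ["X"])
    return u


def write_system(
    topology: Topology,
    frames: Sequence[Frame],
    topology_path: str | Path,
    trajectory_path: str | Path,
) -> None:
    """Write a PDB (first frame, with CRYST1) and a DCD trajectory.

    The pair round-trips through :func:`read_topology` / :func:`read_frames`
    up to format precision (PDB coordinates 3 decimals, DCD single precision).
    """
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    frames = list(frames)
    if not frames:
        raise MemlensError("write_system requires at least one frame")
    for i, fr in enumerate(frames):
        if fr.n_atoms != topology.n_atoms:
            raise MemlensError(
                f"frame {i} has {fr.n_atoms} atoms; topology has {topology.n_atoms}"
            )

    coords = np.stack([fr.coordinates for fr in frames]).astype(np.float32)
    dims = np.zeros((len(frames), 6), dtype=np.float64)
    for i, fr in enumerate(frames):
        if fr.box is not None:
            dims[i, :3] = fr.box
            dims[i, 3:] = 90.0

    u = _build_universe(topology, len(frames))
    u.load_new(coords, format=MemoryReader, dimensions=dims)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.trajectory[0]
        u.atoms.write(str(topology_path))
        with mda.Writer(str(trajectory_path), n_atoms=topology.n_atoms) as w:
            for ts in u.trajectory:
                w.write(u.atoms)
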