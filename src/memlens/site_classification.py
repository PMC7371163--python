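"""PIP2 binding-site classification.

PI(4,5)P2 carries phosphate groups on the inositol-ring carbons C1, C4 and
C5.  The two modelled protonation species are singly protonated at either
the 4- or the 5-phosphate, so each heavy atom of a PIP2 molecule falls into
one of six binding-site categories:

==========  =====================================================
category    meaning
==========  =====================================================
P1np        C1 phosphodiester (non-protonated in both species)
P4p / P4np  C4 phosphate, protonated / non-protonated
P5p / P5np  C5 phosphate, protonated / non-protonated
OTHER       every other heavy atom (ring, glycerol, acyl chains)
==========  =====================================================

For the 4-protonated species the C4 phosphate atoms are ``P4p`` and the C5
atoms ``P5np``; for the 5-protonated species the roles swap.  Per-residue
binding-site ratios report what fraction of a residue's PIP2 atom-pair
contact instances (each pair in each frame counted once) fell in each
category.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import yaml

from .errors import MappingError, NoContactsError
from .trajectory_io import PIP2_SPECIES, Species, Topology

__all__ = [
    "SiteCategory",
    "SiteMap",
    "SiteRatio",
    "DEFAULT_PHOSPHATE_ATOMS",
    "load_phosphate_config",
    "build_site_map",
    "site_ratios",
]


class SiteCategory(str, Enum):
    P1np = "P1np"
    P4p = "P4p"
    P5p = "P5p"
    P4np = "P4np"
    P5np = "P5np"
    OTHER = "OTHER"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Heavy atoms of each phosphate group, CHARMM PIP2 naming: the phosphorus,
#: its terminal/hydroxyl oxygens, and the ester oxygen to the ring carbon.
DEFAULT_PHOSPHATE_ATOMS: dict[str, list[str]] = {
    "P1": ["P", "O11", "O12", "O13", "O14"],
    "P4": ["P4", "O4", "OP42", "OP43", "OP44"],
    "P5": ["P5", "O5", "OP52", "OP53", "OP54"],
}

#: Ester oxygens bridging each phosphate to the inositol ring; excluded from
#: the group when ``include_ester_oxygens=False``.
_ESTER_OXYGENS: dict[str, list[str]] = {"P1": ["O11"], "P4": ["O4"], "P5": ["O5"]}


def load_phosphate_config(path) -> dict[str, list[str]]:
    """Load a phosphate-group atom-name config (YAML/JSON mapping
    ``{P1: [...], P4: [...], P5: [...]}``)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping) or set(raw) - {"P1", "P4", "P5"}:
        raise MappingError(
            f"phosphate config {path} must map exactly P1/P4/P5 to atom-name lists"
        )
    return {k: [str(n) for n in v] for k, v in raw.items()}


def _category_of_group(group: str, species: Species) -> SiteCategory:
    if group == "P1":
        return SiteCategory.P1np
    if group == "P4":
        return SiteCategory.P4p if species is Species.PIP2_P4 else SiteCategory.P4np
    if group == "P5":
        return SiteCategory.P5p if species is Species.PIP2_P5 else SiteCategory.P5np
    raise MappingError(f"unknown phosphate group {group!r}")


@dataclass(frozen=True)
class SiteMap:
    """Per-species mapping of PIP2 heavy-atom names to site categories."""

    by_species: Mapping[Species, Mapping[str, SiteCategory]]

    def category(self, species: Species, atom_name: str) -> SiteCategory:
        if species not in self.by_species:
            raise MappingError(
                f"binding-site categories are undefined for species {species}"
            )
        table = self.by_species[species]
        if atom_name not in table:
            raise MappingError(
                f"atom {atom_name!r} not present in the {species} site map"
            )
        return table[atom_name]


@dataclass(frozen=True)
class SiteRatio:
    """Binding-site occupancy percentages; components sum to 100."""

    P1np: float
    P4p: float
    P5p: float
    P4np: float
    P5np: float
    OTHER: float

    def as_dict(self) -> dict[str, float]:
        return {c.value: getattr(self, c.value) for c in SiteCategory}

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        return {k: round(v, ndigits) for k, v in self.as_dict().items()}


def build_site_map(
    topology: Topology,
    phosphate_atoms: Mapping[str, Iterable[str]] | None = None,
    include_ester_oxygens: bool = True,
) -> SiteMap:
    """Assign every PIP2 heavy atom to exactly one site category.

    Atom names listed for a phosphate group map to that group's category
    (protonation resolved per species); all remaining heavy atoms map to
    ``OTHER``.  A configured phosphate atom name missing from the molecules
    in *topology*, or a topology without PIP2, raises :class:`MappingError`.
    """
    config = {
        k: list(v) for k, v in (phosphate_atoms or DEFAULT_PHOSPHATE_ATOMS).items()
    }
    if set(config) != {"P1", "P4", "P5"}:
        raise MappingError("phosphate config must define exactly P1, P4 and P5")
    if not include_ester_oxygens:
        config = {
            g: [n for n in names if n not in _ESTER_OXYGENS.get(g, [])]
            for g, names in config.items()
        }

    by_species: dict[Species, dict[str, SiteCategory]] = {}
    for species in (Species.PIP2_P4, Species.PIP2_P5):
        molecules = topology.molecules_of_species(species)
        if not molecules:
            continue
        heavy_names: set[str] = set()
        for mol in molecules:
            for i in mol.atom_indices:
                atom = topology.atoms[i]
                if atom.is_heavy:
                    heavy_names.add(atom.atom_name)
        table: dict[str, SiteCategory] = {}
        for group, names in config.items():
            cat = _category_of_group(group, species)
            for name in names:
                if name not in heavy_names:
                    raise MappingError(
                        f"configured phosphate atom {name!r} (group {group}) absent "
                        f"from {species} molecules"
                    )
                if name in table:
                    raise MappingError(
                        f"atom {name!r} assigned to more than one phosphate group"
                    )
                table[name] = cat
        for name in heavy_names - set(table):
            table[name] = SiteCategory.OTHER
        by_species[species] = table

    if not by_species:
        raise MappingError("topology contains no PIP2 molecules to classify")
    return SiteMap(by_species=by_species)


def site_ratios(contact_pairs, site_map: SiteMap, topology: Topology) -> SiteRatio:
    """Binding-site percentages for one residue's PIP2 contacts over a window.

    *contact_pairs* is the flat collection of that residue's PIP2 contact
    pairs across the window's frames (each pair in each frame once); the
    denominator is the total number of such instances.  Zero instances
    raise :class:`NoContactsError` so callers can omit the row, mirroring
    reports restricted to interacting residues.
    """
    counts = {c: 0 for c in SiteCategory}
    total = 0
    names = topology.atom_names
    for pair in contact_pairs:
        if pair.species not in PIP2_SPECIES:
            raise MappingError(
                f"site_ratios applies only to PIP2 contacts, got {pair.species}"
            )
        cat = site_map.category(pair.species, str(names[pair.lipid_atom]))
        counts[cat] += 1
        total += 1
    if total == 0:
        raise NoContactsError("no PIP2 contact instances in the window")
    pct = {c: 100.0 * counts[c] / total for c in SiteCategory}
    return SiteRatio(**{c.value: pct[c] for c in SiteCategory})
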