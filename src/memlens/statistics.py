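"""Per-residue and whole-system contact statistics.

Time-series means are reported with block-averaged standard errors: the
window is split into equal blocks (default 5, e.g. five 200-ns blocks of a
1-µs window) and the SE of the mean is the sample standard deviation of
the block means divided by sqrt(n_blocks).  Frame-level standard
deviations are computed alongside and labelled separately, because window
averages are sometimes quoted with the frame-to-frame SD instead; the two
must not be conflated.

Binding lifetime of a residue is the percentage of window frames with at
least one contact to the lipid species; the partner count is the number of
distinct lipid molecules contacted anywhere in the window (a
maximum-simultaneous variant is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .contacts import ContactSet, normalize_species
from .errors import MemlensError, NoContactsError
from .site_classification import SiteCategory, SiteMap, site_ratios
from .trajectory_io import PIP2_SPECIES, Frame, Species, Topology

__all__ = [
    "AnalysisWindow",
    "block_stats",
    "frame_stats",
    "select_window",
    "lifetime_and_partners",
    "residue_table",
    "distinct_lipid_summary",
    "pair_mean_contacts",
    "DEFAULT_DOMAIN_SPLIT",
]

#: Last residue number of the N-terminal segment (PX + PH domains) in the
#: reference protein; residues beyond it are labelled C-terminal.
DEFAULT_DOMAIN_SPLIT = 325


@dataclass(frozen=True)
class AnalysisWindow:
    """Time window (ns) and block count for block-averaged statistics."""

    start_ns: float
    end_ns: float
    n_blocks: int = 5

    def __post_init__(self) -> None:
        if not self.end_ns > self.start_ns:
            raise MemlensError("end_ns must exceed start_ns")
        if self.n_blocks < 2:
            raise MemlensError("n_blocks must be at least 2 for a standard error")


def select_window(
    frames: Sequence[Frame], window: AnalysisWindow
) -> list[int]:
    """Indices of frames with ``start_ns <= time < end_ns``."""
    return [
        i
        for i, fr in enumerate(frames)
        if window.start_ns <= fr.time_ns < window.end_ns
    ]


def block_stats(
    series, n_blocks: int = 5, allow_ragged: bool = False
) -> tuple[float, float]:
    """Grand mean and block-averaged standard error of a per-frame series.

    The series is split into *n_blocks* contiguous equal blocks; the SE is
    the sample standard deviation (ddof=1) of the block means over
    sqrt(n_blocks).  A series length not divisible by *n_blocks* is an
    error unless *allow_ragged*, which truncates the tail so block sizes
    stay equal and the SE semantics stay clean.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1:
        raise MemlensError("block_stats expects a 1-D series")
    if n_blocks < 2:
        raise MemlensError("n_blocks must be >= 2 (SE undefined otherwise)")
    if x.size < n_blocks:
        raise MemlensError(
            f"series of length {x.size} cannot be split into {n_blocks} blocks"
        )
    if x.size % n_blocks != 0:
        if not allow_ragged:
            raise MemlensError(
                f"series length {x.size} not divisible by {n_blocks} blocks; "
                "pass allow_ragged=True to truncate the tail"
            )
        x = x[: x.size - (x.size % n_blocks)]
    blocks = x.reshape(n_blocks, -1)
    block_means = blocks.mean(axis=1)
    se = float(np.std(block_means, ddof=1) / np.sqrt(n_blocks))
    return float(x.mean()), se


def frame_stats(series) -> tuple[float, float]:
    """Mean and frame-level sample standard deviation of a series."""
    x = np.asarray(series, dtype=np.float64)
    if x.size == 0:
        raise MemlensError("frame_stats requires a non-empty series")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return float(x.mean()), sd


def _resolve_residue(topology: Topology, residue) -> tuple[str, int]:
    residues = {(c, n) for c, n, _ in topology.protein_residues()}
    if isinstance(residue, tuple):
        key = (str(residue[0]), int(residue[1]))
        if key not in residues:
            raise KeyError(f"protein residue {key} not in topology")
        return key
    matches = [k for k in residues if k[1] == int(residue)]
    if not matches:
        raise KeyError(f"protein residue number {residue} not in topology")
    if len(matches) > 1:
        raise KeyError(
            f"residue number {residue} is ambiguous across chains; "
            "pass a (chain, residue_number) tuple"
        )
    return matches[0]


def lifetime_and_partners(
    contact_sets: Sequence[ContactSet],
    residue,
    species=None,
    topology: Topology | None = None,
    partner_mode: str = "distinct",
) -> tuple[float, int]:
    """Binding lifetime (%) and partner count of one residue.

    ``partner_mode="distinct"`` (default) counts lipid molecules of the
    species contacted at least once anywhere in the window;
    ``"max_simultaneous"`` counts the largest number bound in any single
    frame.
    """
    if len(contact_sets) == 0:
        raise MemlensError("lifetime_and_partners requires a non-empty window")
    if topology is not None:
        residue = _resolve_residue(topology, residue)
    wanted = normalize_species(species)
    bound_frames = 0
    partners: set[int] = set()
    max_simultaneous = 0
    for cs in contact_sets:
        frame_partners = {
            p.lipid_molecule
            for p in cs.pairs
            if p.species in wanted and _matches(p.protein_residue, residue)
        }
        if frame_partners:
            bound_frames += 1
            partners |= frame_partners
            max_simultaneous = max(max_simultaneous, len(frame_partners))
    lifetime = 100.0 * bound_frames / len(contact_sets)
    if partner_mode == "distinct":
        n = len(partners)
    elif partner_mode == "max_simultaneous":
        n = max_simultaneous
    else:
        raise MemlensError(f"unknown partner_mode {partner_mode!r}")
    return lifetime, n


def _matches(protein_residue: tuple[str, int], residue) -> bool:
    if isinstance(residue, tuple):
        return protein_residue == (str(residue[0]), int(residue[1]))
    return protein_residue[1] == int(residue)


_SITE_COLUMNS = [c.value for c in SiteCategory]


def residue_table(
    contact_sets: Sequence[ContactSet],
    topology: Topology,
    species="PIP2",
    n_blocks: int = 5,
    min_mean: float = 1.0,
    site_map: SiteMap | None = None,
    allow_ragged: bool = False,
    domain_split: int = DEFAULT_DOMAIN_SPLIT,
    partner_mode: str = "distinct",
) -> pd.DataFrame:
    """Ranked per-residue contact statistics table.

    One row per protein residue whose window-mean atom-pair contact count
    with the species is at least *min_mean* (default 1.0, i.e. only
    residues that actually engage the lipid), ranked by mean descending
    with ties broken by residue number ascending.  Columns: mean/SE
    (block-averaged), frame-level SD, binding lifetime %, partner count,
    and — when the species is PIP2 and a *site_map* is given — the six
    binding-site ratio percentages.
    """
    if len(contact_sets) == 0:
        return pd.DataFrame(
            columns=[
                "rank", "chain", "residue_number", "residue_name", "domain",
                "mean_contacts", "se_contacts", "sd_contacts",
                "lifetime_percent", "n_partners", *_SITE_COLUMNS,
            ]
        )
    wanted = normalize_species(species)
    want_ratios = site_map is not None and wanted <= PIP2_SPECIES

    n_frames = len(contact_sets)
    counts: dict[tuple[str, int], np.ndarray] = {}
    partner_sets: dict[tuple[str, int], set[int]] = {}
    frame_partner_max: dict[tuple[str, int], int] = {}
    frame_partners_now: dict[tuple[str, int], set[int]] = {}
    bound_frames: dict[tuple[str, int], int] = {}
    pair_lists: dict[tuple[str, int], list] = {}

    for t, cs in enumerate(contact_sets):
        frame_partners_now.clear()
        for p in cs.pairs:
            if p.species not in wanted:
                continue
            key = p.protein_residue
            if key not in counts:
                counts[key] = np.zeros(n_frames, dtype=np.int64)
                partner_sets[key] = set()
                frame_partner_max[key] = 0
                bound_frames[key] = 0
                pair_lists[key] = []
            counts[key][t] += 1
            partner_sets[key].add(p.lipid_molecule)
            frame_partners_now.setdefault(key, set()).add(p.lipid_molecule)
            if want_ratios:
                pair_lists[key].append(p)
        for key, mols in frame_partners_now.items():
            bound_frames[key] += 1
            frame_partner_max[key] = max(frame_partner_max[key], len(mols))

    resnames = {(c, n): rn for c, n, rn in topology.protein_residues()}
    rows = []
    for key, series in counts.items():
        mean, se = block_stats(series, n_blocks=n_blocks, allow_ragged=allow_ragged)
        if mean < min_mean:
            continue
        _, sd = frame_stats(series)
        chain, resnum = key
        row = {
            "chain": chain,
            "residue_number": resnum,
            "residue_name": resnames.get(key, ""),
            "domain": "N" if resnum <= domain_split else "C",
            "mean_contacts": mean,
            "se_contacts": se,
            "sd_contacts": sd,
            "lifetime_percent": 100.0 * bound_frames[key] / n_frames,
            "n_partners": (
                len(partner_sets[key])
                if partner_mode == "distinct"
                else frame_partner_max[key]
            ),
        }
        if want_ratios:
            try:
                ratio = site_ratios(pair_lists[key], site_map, topology)
                row.update(ratio.as_dict())
            except NoContactsError:  # pragma: no cover - mean>=min_mean implies pairs
                pass
        rows.append(row)

    df = pd.DataFrame(rows)
    if df.empty:
        return residue_table([], topology)
    df = df.sort_values(
        ["mean_contacts", "residue_number"], ascending=[False, True]
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    for col in _SITE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df


def distinct_lipid_summary(
    contact_sets: Sequence[ContactSet], species=None
) -> tuple[int, float]:
    """How many lipid molecules of a species engage the protein.

    Returns ``(distinct_over_window, mean_per_frame)``: the number of
    molecules with at least one protein contact anywhere in the window, and
    the average per-frame count of interacting molecules.  Both are
    reported because "on average, N lipids interacted" can mean either.
    """
    if len(contact_sets) == 0:
        raise MemlensError("distinct_lipid_summary requires a non-empty window")
    wanted = normalize_species(species)
    overall: set[int] = set()
    per_frame = np.zeros(len(contact_sets), dtype=np.int64)
    for t, cs in enumerate(contact_sets):
        mols = {p.lipid_molecule for p in cs.pairs if p.species in wanted}
        overall |= mols
        per_frame[t] = len(mols)
    return len(overall), float(per_frame.mean())


def pair_mean_contacts(
    contact_sets: Sequence[ContactSet], topology: Topology, species=None
) -> pd.DataFrame:
    """Window-mean atom-pair contact count per (residue, lipid molecule).

    This is the edge table the interaction network is built from: one row
    per residue-lipid pair that ever touched, with the mean over all frames
    of the window (frames without contact contribute zero).
    """
    if len(contact_sets) == 0:
        return pd.DataFrame(
            columns=[
                "chain", "residue_number", "domain", "lipid_molecule",
                "species", "mean_contacts",
            ]
        )
    wanted = normalize_species(species)
    n_frames = len(contact_sets)
    totals: dict[tuple[tuple[str, int], int], int] = {}
    mol_species: dict[int, Species] = {}
    for cs in contact_sets:
        for p in cs.pairs:
            if p.species not in wanted:
                continue
            key = (p.protein_residue, p.lipid_molecule)
            totals[key] = totals.get(key, 0) + 1
            mol_species[p.lipid_molecule] = p.species
    rows = [
        {
            "chain": chain,
            "residue_number": resnum,
            "domain": "N" if resnum <= DEFAULT_DOMAIN_SPLIT else "C",
            "lipid_molecule": mol,
            "species": mol_species[mol].value,
            "mean_contacts": total / n_frames,
        }
        for ((chain, resnum), mol), total in totals.items()
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "chain", "residue_number", "domain", "lipid_molecule",
            "species", "mean_contacts",
        ],
    )
    return df.sort_values(
        ["chain", "residue_number", "lipid_molecule"]
    ).reset_index(drop=True)
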