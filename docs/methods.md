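# Methods

This note documents the models, conventions and numerical choices behind
`memlens`, and what the synthetic validation does and does not show.

## Contact definition

A contact is an (protein heavy atom, lipid heavy atom) pair whose
distance is **strictly less than** the threshold `r_c` (default 3.5 Å).
Hydrogens never participate; solvent, ions and protein–protein or
lipid–lipid pairs are never counted. "Number of contacts" of a residue
is the number of such atom *pairs*, not the number of distinct atoms —
a residue whose guanidinium nitrogen bridges two phosphate oxygens
contributes two contacts. The strict inequality and the pair-counting
convention are both configurable points in `ContactParams` /
`find_contacts`, but the defaults define the package's semantics and are
what the test-suite pins down.

Distances obey the minimum-image convention in an orthorhombic box: each
Cartesian component of the separation is reduced by the nearest integer
multiple of the box length. For orthorhombic cells the per-axis
reduction equals the minimum over all 27 translated images (the axes are
independent), which the tests verify against explicit enumeration.
Consequently the analysis is invariant under arbitrary rigid
translations and under per-molecule rewrapping — trajectories may be
wrapped or unwrapped. Triclinic cells are rejected rather than silently
mishandled.

### Cell list

The production search hashes lipid atoms into cells of width
`box/floor(box/r_c) ≥ r_c` and, for each protein atom, examines the 27
neighbouring cells (with periodic wrap-around; duplicate cells that
arise in 2-cell axes are deduplicated). An error is raised when
`r_c > box/2` in any axis, where a single-image search is not valid.
The cell list is contractually identical to the O(N²) all-pairs
computation; the tests and the acceptance script enforce equality of the
full pair set on random instances.

## Binding-site categories

PI(4,5)P₂ carries phosphates on the inositol C1, C4 and C5 carbons, and
the two modelled protonation species are singly protonated at P4 or P5.
Each PIP2 heavy atom maps to exactly one of six categories: P1np, P4p,
P5p, P4np, P5np, OTHER. A phosphate group comprises the phosphorus,
its terminal/hydroxyl oxygens and the ester oxygen to the ring carbon
(CHARMM naming: `P O11 O12 O13 O14`, `P4 O4 OP42 OP43 OP44`,
`P5 O5 OP52 OP53 OP54`); including the ester oxygen is a choice —
"heavy atoms of the phosphate group" does not uniquely enumerate atoms —
and is configurable (`include_ester_oxygens`). All remaining heavy atoms
(ring, glycerol, acyl chains, ring hydroxyl oxygens) fall in OTHER.

A residue's site ratio over a window is the percentage of its PIP2
contact *instances* (each pair in each frame counted once) per category.
The denominator is the total instance count, so the ratio is invariant
under frame reordering and uniform duplication of frames. A window with
zero PIP2 instances has no defined ratio and is signalled distinctly
(`NoContactsError`), so reporting code can omit the row. Reported
precision is one decimal place.

## Per-residue statistics

* **Mean ± SE** — the window's per-frame pair-count series is split into
  `n_b` contiguous equal blocks (default 5, e.g. five 200-ns blocks of a
  1-µs window). The mean is the grand mean; the SE is the sample
  standard deviation (ddof = 1) of the block means divided by `√n_b`.
  A window length not divisible by `n_b` is an error by default;
  `allow_ragged` truncates the tail so block sizes stay equal — ragged
  blocks would silently change the SE semantics. `n_b < 2` is an error
  (no SE exists).
* **Frame-level SD** — reported alongside, labelled `sd_contacts`,
  because window averages of contact time-profiles are sometimes quoted
  with the frame-to-frame standard deviation rather than the block SE;
  computing both prevents conflating two quantities that can differ by
  an order of magnitude on correlated series.
* **Binding lifetime** — 100 × (frames with ≥ 1 contact of the residue
  with any molecule of the species) / (window frames).
* **Partner count** — the number of *distinct* lipid molecules of the
  species contacted anywhere in the window. Small integer partner
  counts alongside ~100% lifetimes are consistent with this cumulative
  reading; the maximum-simultaneous alternative is available via
  `partner_mode="max_simultaneous"` but is not the default.
* **Table** — one row per residue with mean ≥ `min_mean` (default 1.0,
  i.e. only residues genuinely engaging the lipid), ranked by mean
  descending, ties broken by residue number ascending for determinism.
  The domain column labels residues ≤ 325 as N-terminal (PX + PH
  domains) and the rest C-terminal; the split point is a parameter.
* **Distinct-lipid summary** — both the count of molecules with ≥ 1
  protein contact anywhere in the window and the mean per-frame count of
  interacting molecules are returned, because the phrase "on average, N
  lipids interacted" can denote either; on constant schedules the two
  coincide.

## Interaction network

Nodes are protein residues and individual lipid molecules; an undirected
edge joins a residue to a lipid molecule when their window-mean pair
count is ≥ 1.0 (the inclusion threshold; a strict `>` variant is
available). Edges carry the mean as weight. The graph is bipartite by
construction, so the handshake identity (sum of residue degrees = sum of
lipid degrees = edge count) is an invariant, and clusters are connected
components, ordered by size descending then smallest node id.
Components are computed on the union network (PIP2 and POPA edges
together), since mixed-lipid clusters are precisely the interesting
objects. GraphML export carries kind/species/domain/degree/component
attributes and loads into Cytoscape; layout and visualisation are out of
scope.

## File I/O

MDAnalysis handles PDB and DCD reading/writing. Heavy-atom flags come
from the element column, falling back to a name heuristic (strip leading
digits; a leading H means hydrogen) because PDB dialects often leave the
element blank. Residue numbering is preserved exactly as input.
Protein atoms group into one molecule per chain; lipids, water and ions
into one molecule per (residue name, residue number, chain). Frame
times are `index × frame_interval` with a 240 ps default interval,
because trajectory-format time headers are dialect-dependent; the
interval is a parameter everywhere. A single CRYST1 record preceding
the first MODEL of a multi-model PDB is applied to every model. Species
classification is driven by a residue-name → species table (CHARMM
names by default, YAML-overridable); the 4-character aliases `PI24` /
`PI25` for the two PIP2 species exist because the PDB residue-name
column cannot hold six characters.

## Synthetic data

`make_composition` reproduces the reference 600-lipid leaflet rows at
10% and 1% PIP2 exactly (outer leaflet PIP2/POPA-free, PIP2 split 1:1
between the two protonation species, 144 waters per lipid, 0.15 M
salt). For other percentages it sets PIP2 = POPA = round(percent ×
leaflet), keeps sphingomyelin, and fills the remainder with
cholesterol/POPC/POPE in proportions linearly interpolated between the
two reference rows, using largest-remainder rounding so leaflet totals
are always conserved. Interpolating all three filler lipids (rather
than rebalancing POPC/POPE alone) was chosen because the two reference
rows differ in cholesterol as well.

`make_toy_system` places simplified residues (4–8 heavy atoms, 6 Å
apart) on a mid-plane grid and coarse lipids (named headgroup atoms +
tail beads) on leaflet grids ~25 Å above and below, so every
non-planted protein–lipid pair is separated by far more than
`r_c + margin` (margin 0.5 Å). Planted contacts are realised exactly:
the requested lipid atom (drawn from the requested phosphate group, so
the site category is known) is placed at the stated distance below a
protein atom of the target residue; distinct atoms are allocated per
frame so *k* planted pairs yield exactly *k* detected pairs, and
oversubscription raises a generation error. Cross-boundary contacts
displace the lipid atom by one full box length, so the unwrapped
distance is large but the minimum image equals the planted value.
Coordinates are rounded to 0.001 Å (PDB precision), and the only
randomness is small grid jitter from a seeded generator, so systems are
bit-reproducible for a fixed seed.

What the toys do **not** emulate: molecular connectivity and realistic
geometry (a planted lipid's contact atom detaches from its parked
body), thermal motion, lipid diffusion, membrane curvature, solvent and
ions. Passing tests therefore demonstrate the *correctness of the
analysis arithmetic* — contact detection, statistics, classification,
networks — not anything about real membranes. Conclusions about a real
system require a real trajectory.

## Validation problem sizes

The test-suite and acceptance script use: 1000 random point pairs
against 27-image enumeration; 20 random 500-atom frames against the
all-pairs oracle; 50 random bipartite graphs against a BFS component
oracle; schedule trajectories of 4–10 frames with up to 60 PIP2
molecules; and a 50-frame, ~1300-atom end-to-end pipeline run. These
sizes give exact, exhaustively checkable ground truth while keeping the
whole suite in seconds.

## Known limitations

* Orthorhombic boxes only; triclinic cells are rejected.
* `r_c` must not exceed half the shortest box edge.
* Statistics assume the trajectory frames are the analysis window; block
  averaging mitigates, but does not model, temporal correlation
  (autocorrelation-based error estimates are out of scope).
* Contact counting is pairwise and geometric; no hydrogen-bond or
  salt-bridge geometry, no residence-time distributions, no free
  energies.
* Residue numbers above 9999 or residue names beyond 4 characters do
  not survive a PDB round trip (format limits).
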