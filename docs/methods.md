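# Methods

## The measurement

The package compares the binding interface between GPCRs and heterotrimeric
G proteins across structures of receptor–G protein complexes. Three
conventions define the measurement and are fixed package-wide:

**Contact criterion.** A contact is an inter-chain residue pair whose
minimum heavy-atom distance is *strictly* below the threshold (default
4.0 Å). All heavy atoms participate, backbone and side chain alike;
hydrogens are excluded because deposited complexes at typical cryo-EM/X-ray
resolutions carry none, and dropping any that are present keeps maps
comparable across files. The boundary is exclusive (a pair at exactly
4.00 Å is not a contact) and is covered by an explicit test. Distances are
*reported* to 0.01 Å but *compared* unrounded.

**Common frame.** Complexes are superposed by a least-squares rigid fit
(Kabsch, via SVD with a determinant sign correction that forbids
reflections) on the Cα atoms of the Gα α5 positions H5.11–H5.26 — the
C-terminal stretch of Gα that carries most receptor contacts. All frame
atoms are weighted equally; a frame label that cannot be resolved to a Cα
in either structure is a hard error rather than a silent fit-on-subset, so
frames stay strictly comparable across a cohort. The reference structure is
an explicit argument, recorded in the output metadata, because no single
canonical reference exists. Orthonormality of rotations is checked to 1e-6.

**Generic coordinates.** Receptor positions use Ballesteros–Weinstein
numbering (`5.68`; `12.xx` for the TM1–TM2/ICL1 region, `8.xx` for helix 8),
Gα positions use CGN (`H5.17`, `G.S6.02`), and Gβ residues carry a
β-propeller blade annotation. The author residue number plus insertion code
is the canonical key throughout, since structure papers cite author numbers;
mmCIF label_seq is never used. Mapping tables are consumed, not computed:
the package does not derive BW or CGN numbering from geometry. Blade
annotations span many residues per blade, so mapping rows may carry a
segment with no unique label (label column `.`); unique-label rows and
segment-only rows coexist in one table.

The α5 helix is defined as the last 26 residues of Gα, generic positions
H5.01–H5.26; the superposition frame is H5.11–H5.26 and the C-terminal
"hook" is H5.22–H5.26. All three ship as named label sets
(`alpha5`, `alpha5_frame`, `alpha5_hook`).

## Selection policies

Coordinate files are reduced deterministically before any measurement:
only model 1 of a multi-model file is kept; for alternate locations the
highest-occupancy conformer wins, ties broken by the lexicographically
smallest altloc id (idempotent); waters, ligands, ions and detergent are
stripped, keeping polymer amino-acid residues only — a non-standard residue
on a polymer chain (e.g. a modified cysteine) is retained and its heavy
atoms participate in contacts. Polymer status comes from the mmCIF entity
classification, or for PDB files from the ATOM/HETATM record combined with
an amino-acid name check. These policies are embedded in every contact
map's provenance block. Fab/nanobody chains carry the `stabilizer` role in
cohort manifests and are excluded from interface runs by default; the role
assignment is the user's decision.

## Conservation and specificity

Per-complex receptor–Gα contact maps are merged into a presence matrix
keyed by (Gα generic position, receptor key). The receptor key is either a
single BW position or a segment name: segment resolution exists because
subtype anchors are naturally stated against segments ("the TM7/H8 turn",
"TM6") while the Gα side is always one generic position. At segment
resolution a pair is present in a complex iff at least one residue of the
segment touches that Gα position.

"Conserved in a group" means present in 100% of the group's members; the
fraction is configurable (`conserved_fraction`) for exploration but
defaults to 1.0 — conservation is an intersection, so adding a member can
only shrink a group's conserved set (tested as a property).
"Subtype-specific" means conserved in exactly one of the cohort's groups;
single-group cohorts cannot support specificity claims and return their
conserved rows flagged `non_specific`. Conservation is positional, never
identity-based: residue identities at each position (Tyr vs Phe at H5.26)
are attached to the report but not required to match.

A complex may lack a pair either because the distance exceeds the cutoff
or because the segment is not modeled (disordered loops are routine,
especially ICL3). When the caller supplies the set of segments with
modeled residues per complex, absence-by-disorder is flagged `U`
(unresolved) in the atlas instead of `0`; `U` still counts as absent for
conservation, which is the conservative choice.

## C-tail accounting

The receptor C-terminal tail is defined by an author-numbered window
(`full_length_tail`) and the modeled sub-window (`tail_range`), both
construct-specific and user-overridable. The shipped bovine rhodopsin
definition uses the 25-residue window 324–348 with modeled range 324–335
(hence "12 of 25", 48%), hinge residues 324/327/329, and phosphosites
334/336/338/340/342/343 carried as static bookkeeping for cross-state
comparison. The two palmitoylated cysteines 322–323 sit outside the tail
window. Tail partner lists are by construction identical to the rows of
the full receptor–Gα and receptor–Gβ contact maps restricted to the tail
window (tested as a cross-module consistency property).

## Numbering transfer

Labels can be transferred from an annotated reference sequence to a query
by global pairwise alignment (Needleman–Wunsch with affine gaps) with
match +2, mismatch −1, gap open −10, gap extend −0.5 — deliberately
gap-averse, since transfer is only sane between close homologs. A gap of
length k costs open + (k−1)·extend. Labels cross only aligned non-gap
columns, and transfer is refused below 30% alignment identity
(identical positions / longer sequence length). The implementation is
Biopython's `PairwiseAligner`; the test suite checks its scores against an
independent Gotoh dynamic-programming oracle on short sequences and the
identity-transfer property on random sequences. Map keys on both sides of
a transfer are 1-based sequence positions. Multiple-sequence alignment is
out of scope; transfer is pairwise only.

## Synthetic ground truth

The generator builds ideal α-helices (rise 1.5 Å/residue, twist
100°/residue, Cα radius 2.3 Å — standard α-helix geometry) with one pseudo
side-chain atom per residue at a fixed radial offset (1.5 Å beyond Cα).
One pseudo atom suffices because the contact criterion is any-atom
distance; no claim of physical packing is made.

Planted contacts are exact by construction: chains are laid out 150 Å
apart, and each planted pair is realised by a single probe atom attached
to the partner residue at precisely the requested distance from the target
residue's outermost body atom, directed away from the helix body. Probes
anchored on one residue but belonging to different partner chains get base
directions 90° apart in the radial/tangential plane so they cannot form
spurious contacts with each other. Two guarantees are enforced by a
brute-force post-verification (and raise `PlacementError` if a spec
defeats them): every planted pair's minimum distance is within 1e-3 Å of
target, and every unplanned inter-chain pair stays above 4.5 Å — a 0.5 Å
guard band around the 4.0 Å threshold that makes truth maps unambiguous
under float noise. Conflicting targets for one residue pair are rejected
up front. Because of the 90°-separation geometry, two planted distances
below ~3.2 Å cannot share an anchor residue across two partner chains;
the post-verification reports such specs as infeasible.

Synthetic cohorts plant a conserved (Gα label, receptor key) pattern into
every member of a subtype group, plus per-member noise contacts drawn from
a seeded generator. The noise invariant — no noise pair present in every
member of any group — is what guarantees noise can never masquerade as a
conserved anchor; it is enforced after drawing and validated again before
any file is written. A single integer seed governs all randomness; equal
seeds give byte-identical output trees. The member template covers the
cytoplasmic interface segments (TM3, ICL2, TM5, TM6, TM7, H8, C-tail on a
60-residue receptor chain; a 26-residue Gα α5 labeled H5.01–H5.26), which
is the portion of a receptor the interface analysis actually reads.

What the generator does **not** emulate: real side-chain geometry and
packing, backbone atoms beyond Cα/pseudo-Cβ, unmodeled-loop gaps,
alternate conformations, or experimental coordinate error. Passing tests
on synthetic cohorts therefore demonstrate the correctness of the
*bookkeeping and algorithms* (contact enumeration, frame fitting,
conservation intersection, tail accounting) — not the biological claims
about any particular deposited structure, which require running the same
pipeline on real coordinate files with curated numbering tables.

## Problem sizes and numerics

Test and acceptance runs use deliberately small inputs: random two-chain
structures of ~25 residues for the brute-force contact oracle (100
structures), 12-point sets for Kabsch recovery (50 random rigid motions,
recovery to 1e-6), and 50 random two-group cohorts of 4 members per group
(2–4 planted pairs, up to 6 noise pairs per member) for anchor-pattern
recovery, which is required to be exact (precision = recall = 1). The
contact search uses a k-d tree internally, but the contract is defined by
the all-pairs brute force and the equivalence is tested to 1e-9 Å. PDB
coordinate fields carry three decimals, so file round trips are checked to
1e-3 Å. Degenerate superposition inputs (fewer than three points, or
collinear point sets) raise a dedicated error rather than returning an
ill-defined fit.

## Known limitations

* Real deposited structures and GPCRdb numbering tables are consumed, not
  bundled; the shipped rhodopsin–Gi table contains only the published
  residue↔label correspondences for that complex, and real-cohort runs
  require user-supplied tables for every member.
* Contacts are inter-chain only by default; intra-receptor contacts (e.g.
  the C-tail folded against its own cytoplasmic face in an inactive-state
  structure) are out of the default path.
* No solvent-accessible-surface, hydrogen-bond typing, electrostatics or
  energy scoring: the criterion is purely geometric distance.
* No map/density handling, symmetry expansion or assembly generation.
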