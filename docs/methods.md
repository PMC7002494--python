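# Methods

## The problem

A protein crystal contains many more protein–protein contacts than the
deposited asymmetric unit shows: space-group symmetry and lattice
translations generate chain copies whose interfaces may be biologically
functional dimers or mere packing artifacts.  A single crystal cannot
distinguish the two.  The observation this toolkit operationalizes is
statistical: when homologous proteins crystallize in *different* crystal
forms, packing contacts vary from form to form, while a genuinely
functional interface tends to recur.  An interface observed in many
independent crystal forms of many homologs is therefore strong evidence
for a biological assembly.  `xtalface` computes that evidence: it
enumerates every unique interface in each crystal's lattice, groups the
entries into crystal forms, and clusters homologous interfaces across
forms, reporting for each cluster the number of crystal forms, entries
and distinct proteins that contain it.

## Lattice census

Chain copies are generated as chain × space-group operator × one of the
27 cell translations of a 3×3×3 block around the reference cell, in the
orthogonal frame (standard crystallographic orthogonalization, **a**
along x).  Interfaces are enumerated between the identity asymmetric-unit
copies and all placements; because every interface class in the crystal
touches an identity copy by symmetry, this anchoring loses nothing, and
enumerating from all copies would only produce duplicates of the same
classes.  Candidate pairs are pre-filtered by axis-aligned bounding boxes
inflated by the Cβ cutoff plus a 5 Å margin — a guaranteed superset of
every pair that can satisfy the contact cutoffs.

Two chains or domains interact iff they have ≥ 10 Cβ–Cβ pairs within
12 Å **and** ≥ 1 heavy-atom contact within 5 Å, **or** ≥ 5 heavy-atom
contacts within 5 Å.  Glycine, which has no Cβ, contributes its Cα
instead, keeping the rule total.  Hydrogens are ignored throughout (most
X-ray entries lack them); for residues with alternate conformations the
highest-occupancy conformer is kept, ties resolved to the alphabetically
first altloc code.

Duplicate lattice interfaces are collapsed by an operator-algebra-free
rule: two interfaces of one crystal are the same class iff their
residue-level contact sets coincide under the identity sequence
correspondence (residues tagged by entity sequence and position, so chain
renaming is irrelevant); the representative is the lexicographically
smallest placement pair.  Domain-level interfaces are carved out of the
chain-level contact sets by the annotated residue intervals, and
intra-chain domain pairs are kept with an `intra_chain` flag.

## Buried surface area

Interface area is half the solvent-accessible surface area (SASA) lost on
complexation, (SASA_a + SASA_b − SASA_ab)/2, clamped at zero.  SASA is
computed with Shrake–Rupley sphere sampling: probe 1.44 Å, 960 points per
atom on a deterministic Fibonacci lattice (bitwise reproducible across
runs), standard van der Waals radii.  At 960 points the fixture-dimer
area agrees with a 9600-point recomputation to < 0.1%.  Chain interfaces
below 100 Å² and domain interfaces below 150 Å² stay in the census with a
`below_bsa` flag but are excluded from clustering; both cutoffs are
config fields because reasonable analyses use either scale.

## Comparing interfaces across homologs: the Q score

Interfaces from non-identical proteins are compared in the family
profile-HMM coordinate system: each annotated residue carries its model
match position, so homologous positions align without a sequence
alignment.  A correspondence is accepted when the common mapped positions
cover ≥ 80% of the shorter domain; identical sequences fall back to plain
sequence-position correspondence.  At chain level, per-domain maps are
concatenated in architecture order and the common coordinate is (domain
index, model position); whether a single chain-wide alignment would be
preferable is undetermined by the evidence we have, and the per-domain
reading is the implemented interpretation.

The similarity of two interfaces is

    Q = |C_a ∩ C_b| / |C_a ∪ C_b|

where C_x is the set of mapped contact pairs of interface x — a Jaccard
index with unit weights (a weight hook exists for non-uniform schemes;
with unit weights the definitional boundary values Q = 1 for an identical
interaction mode and Q = 0 for no shared contacts hold exactly).  For
same-family (homodimer-like) interfaces the side labelling is arbitrary,
so both side pairings are evaluated and the maximum taken.  Pairs with no
admissible correspondence have undefined Q; they contribute 0 to linkage
averages, which keeps incomparable interfaces out of common clusters
without distorting the matrix.

Clustering is hierarchical average linkage: start from singletons,
repeatedly merge the two clusters with the highest average inter-cluster
Q, stop when that best average falls below 0.30.  Ties are broken by the
smallest lexicographic member id; the partition is invariant under input
order and, on random matrices, identical to a reference dendrogram
implementation cut at the same rule.  Each cluster is annotated with the
crystal-form / entry / protein counts, mean buried area, minimum pairwise
global-alignment sequence identity (matches over alignment columns), and
the fraction of members present in deposited author and software-derived
assemblies (an interface "is present" in an assembly when the assembly
contains an interface with Q ≥ 0.85 against it — `q_high`, chosen well
above the 0.30 cluster threshold and below identity, configurable).

## Crystal forms

Entries share a crystal form iff they have (1) the same entry-level
family architecture (the set of distinct chain architectures; chain
counts are rule 3's job), (2) the same space group, (3) the same
asymmetric-unit stoichiometry, and (4) every cell edge and angle within
1% (|x₁−x₂|/max ≤ 0.01).  The 1% relation is not transitive, so forms
are connected components of the pairwise relation — deterministic and
order-independent.  Forms whose interface censuses are essentially the
same lattice merge: interfaces are greedily matched by best Q, and if
matches at Q ≥ 0.85 cover at least two thirds of the smaller census the
forms become one.  This handles the classic case of one lattice solved
both as a monomeric asymmetric unit with N operators and as a dimeric one
with N/2.

## Peptides

A peptide is a polypeptide chain shorter than 30 residues — declared
polymer length, including unmodeled residues, since being a peptide is a
property of the molecule, not of the model.  The domain–peptide contact
rule is ≥ 10 Cβ pairs within 12 Å **or** ≥ 5 atomic contacts within 5 Å
(a deliberate OR, more permissive than the chain rule).  A peptide
touching several chains is assigned to the chain holding ≥ 75% of its
atomic contacts; with no dominant chain, all its interfaces are kept.
Peptide interfaces are collected from the asymmetric unit plus the
expanded lattice, so symmetry-completed grooves are seen, and
deduplicated like chain interfaces.

Two binding modes are compared by N_hmm — the number of family-model
positions both domains contact with their peptides (contact sites are
residues with an atomic contact ≤ 5 Å; a Cβ-only interface falls back to
its Cβ-pair residues) — and by RMSD_pep: superpose the two domains on
their common model positions (least-squares, Kabsch), carry the second
peptide along, and take the minimum peptide Cα RMSD over all ungapped
residue alignments with ≥ 3 overlapping positions.  The peptides are
deliberately *not* refit to each other: the score must reflect where on
the domain the peptide sits, which is what distinguishes binding modes.
Clusters grow greedily by largest average shared-site count while the
average N_hmm ≥ 3 and average RMSD_pep ≤ 10 Å over cross-cluster pairs
(average linkage, mirroring the interface clustering); domain pairs with
fewer than three common positions cannot be superposed and never merge.

## Ligands and nucleic acids

Every non-polymer component except water is a ligand.  A domain–ligand
interaction is ≥ 1 heavy-atom contact within 4.5 Å, computed on the
asymmetric unit; covalently attached components count like any other.
Each interaction is profiled by the set of contacted model positions, and
within one family the ligand instances are clustered by average-linkage
on the Jaccard overlap of those sets with a 0.5 threshold (the overlap
measure and threshold are this package's quantification of
"shared contact positions"; both are config fields).  This separates,
e.g., an active site from an allosteric site.  Nucleic-acid chains run
through the same 4.5 Å contact machinery but are taken from the
biological assemblies, keeping per domain instance only the interface
contacting the most model positions (ties to the smallest assembly id,
then chain id; with no assembly defined the asymmetric unit is used with
a warning).

## Synthetic data

The generator builds ideal-geometry α-helical folds by NeRF chain
construction (ideal bond lengths/angles, φ = −57°, ψ = −47°, Cβ at the
ideal tetrahedral position) and places two copies as an antiparallel
designed dimer 8.8 Å between axes — comfortably inside the interaction
rule (≈ 220 Cβ pairs, ≈ 25 atomic contacts at 32 residues).  Crystals are
written as valid mmCIF with coordinates quantized to 10⁻³ Å so files
round-trip exactly.  Three study conditions are emulated:

* **Homolog benchmark** — k crystal forms (default 3) of sequence
  homologs (10% per-position mutation rate; coordinates are
  sequence-independent, isolating the bookkeeping from geometry), each
  with a rotated asymmetric unit, a distinct cell, and a form-specific
  unrelated "crowder" chain leaning on the dimer's outer face as the
  lattice contact.  Only the designed interface recurs across forms.  An
  optional extra form omits the dimer.  The synthetic family model is the
  fold's own residue index (identity map, coverage 1).
* **Peptide complexes** — a 34-residue domain with an 8-residue peptide
  on one of two opposite faces (two genuine binding modes ~16 Å apart);
  a leading-extension variant shares the C-terminal window bit-for-bit,
  so the minimum-RMSD alignment offset is known exactly.
* **Ligand/nucleic entries** — two disjoint designed contact sites at
  the domain ends; DNA stand-ins (P/C1′ ladder) in two assemblies with
  unequal (or, for tie tests, equal) contacted-position counts.

What the generator does **not** emulate: real side chains and rotameric
packing, solvent, experimental noise and missing density, non-helical
folds, sequence–structure coupling, and realistic space-group diversity
beyond P1/P2₁.  Passing tests therefore demonstrate the correctness of
the census, similarity and clustering machinery under controlled
geometry — not parser robustness against the full variety of deposited
PDB entries.

## Numerical choices and degenerate inputs

* Cutoff comparisons are inclusive (≤) everywhere; boundary tests pin
  4.4/4.6 Å around the ligand rule and 29/30 around the peptide rule.
* The identity placement returns deposited coordinates bit-equal (no
  matrix round trip), so ASU-only analyses are exact.
* Q on two empty contact sets is an error, not 0/0; valid interfaces
  cannot produce it.
* Buried area is clamped at 0 against sampling noise; non-touching pairs
  score 0 within ±0.5 Å².
* Entries without a cell or space group raise a specific
  non-crystallographic error for lattice work but remain usable for
  assembly and ligand analyses.
* Every threshold lives in `PipelineConfig`; a config-override test
  verifies that changing a cutoff propagates downstream (no stage
  hard-codes a literal).
* Average-linkage is O(n³) in cluster count with vectorized averages —
  ample for desk-scale censuses (hundreds of interfaces per family
  pair).

## Problem sizes

Default test and acceptance runs use 32-residue folds (two- or
three-chain asymmetric units, ≈ 160 atoms per chain), benchmark sets of
3–4 entries, 100 random contact fixtures and 200 random similarity
matrices of up to 50 items.  These sizes exercise every code path,
including lattice expansion of up to 216 placements per entry, while
keeping a full run in tens of seconds.

## Known limitations

* Cells are compared as deposited; equivalent cells in non-standard
  settings (no Niggli reduction) can split a crystal form in two.  The
  two-thirds merge step usually reunites them only if architectures
  match.
* Clustering is reported per family pair; clan-level cross-family
  clustering is out of scope (clan keys are carried as annotation only).
* Chain-level correspondence requires equal architectures on the
  compared sides; chains without any domain annotation can only be
  compared to sequence-identical chains.
* The PyMOL-style per-cluster coordinate archives are minimal (plain
  multi-model PDB export of the lattice for inspection); no rendering.
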