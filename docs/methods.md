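# Methods

## Data model

A structure ensemble is an ordered list of frames sharing one topology
(identical `(chain, residue, insertion, atom-name)` sequences); multi-model
PDB files are the on-disk form, with each MODEL one frame. This is a
deliberate stand-in for an MD trajectory: the analyses here only need
coordinates per frame, not velocities or time steps. Hydrogens are kept in
the data model but excluded from every "heavy-atom" computation; alternate
locations collapse to the highest-occupancy conformer (first on tie);
residue numbering follows the file verbatim. Parsing and writing go through
biotite; coordinates survive a round trip to the PDB fixed-column precision
of 1e-3 Å.

Van-der-Waals radii are the Bondi set, shipped as a versioned JSON table and
immutable at run time, so clearance-based results are reproducible
bit-for-bit. Unknown elements raise rather than defaulting: a silent 1.5 Å
guess would corrupt every clearance downstream.

## Active-site descriptor

Given k site atoms resolved in a reference frame, the descriptor stores all
k(k−1)/2 pairwise distances. Using the complete pair set (rather than a
hand-picked subset) fully determines the site geometry up to chirality and
removes an arbitrary choice; with the typical k = 4 that is 6 distances.
The frame score is the sum of absolute per-pair deviations. An additive
signed convention would let opposite-signed distortions cancel and score a
badly distorted site as "similar"; since the score's purpose is a
similarity ranking (low S = close to the bound-state geometry), the
absolute-value form is the default and the signed form is behind a flag for
comparison experiments. S is invariant under rigid motion because only
internal distances enter.

Frame selection for docking combines two criteria: choke-point diameter ≥ a
threshold (default 4.0 Å — approximate clearance for an aromatic ring;
configurable, no canonical value exists) and ascending S among the
survivors, ties broken by lower frame index.

## Tunnel detection

The published tools in this space (CAVER-style) do not document internals
sufficiently for re-derivation, so the search here is a declared,
self-contained method with the same behavioural contract:

1. Regular grid (default spacing 0.5 Å) over the padded bounding box.
2. Node weight = clearance: distance to the nearest heavy-atom vdW surface,
   computed from a k-d tree over atom centers; because radii vary, the 24
   nearest centers are checked and the minimum of (distance − radius) taken.
3. Nodes with clearance < probe radius (default 1.4 Å, water) are removed.
4. Widest-path search (Dijkstra variant maximising the minimum clearance
   along the path) from the start node; 6-connectivity.
5. A boundary node is a bulk-solvent exit when the sphere of radius
   `shell_radius` centred `shell_depth` outward of it (outward = away from
   the atom centroid) contains **no atom centers**; defaults 6 Å / 6 Å.
   Checking centers rather than surfaces makes the criterion slightly
   permissive, by at most one vdW radius — irrelevant at the 6 Å scale.
6. Exits within `shell_radius` of each other are merged, keeping the widest
   representative; the merge radius is tied to the exit-classification
   length scale on purpose.

The discretisation error of the bottleneck radius is bounded by the grid
spacing (verified by the refinement tests at 1.0/0.5/0.25 Å); positions are
accurate to one spacing.

Choke-point diameters are computed independently of the grid: minimum over
heavy-atom pairs of surface-to-surface distance between the two bottleneck
residues. Which atoms of a published bottleneck pair were tracked is
generally not recoverable from figures, so the closest-heavy-atom convention
is the default and a side-chain-centroid mode is available; the mode is
recorded in outputs. Negative diameters are meaningful (interpenetrating
surfaces, e.g. a formed salt bridge). Salt bridges use the standard
side-chain donor/acceptor atoms (Arg NE/NH1/NH2, Lys NZ, His ND1/NE2 vs
Glu OE1/OE2, Asp OD1/OD2) with a 4.0 Å N–O cutoff; a residue lacking those
atoms raises, distinguishing truncated models from absent interactions.

## Superposition

Least-squares rigid superposition is the closed-form Kabsch solution
(SVD of the covariance, reflection corrected to det +1), authored here and
cross-checked in tests against scipy's independent `align_vectors`
implementation. Cross-homolog RMSDs pair residues through a
sequence-alignment-derived residue-number map and match atoms by name
within paired residues.

## Conservation

Per-column score = 1 − H/log 20 with H the Shannon entropy of amino-acid
frequencies, gaps and 'X' excluded; all-gap columns are missing values and
columns with > 50 % gaps are flagged unreliable. This is a deliberately
simple substitute for Bayesian, phylogeny-aware rate estimation: it ranks
columns for conserved/variable flags without trees or priors, and every
output is tagged with the method name so it cannot be mistaken for a
ConSurf-style score. Pairwise alignment is Biopython's global
affine-gap aligner (BLOSUM62, open 10 / extend 0.5 by default, recorded in
the map's provenance; a gap of length L costs open + (L−1)·extend). Among
co-optimal alignments the aligner's first result is taken; the score, which
is what the oracle tests compare, is tie-independent. Projection writes each
residue's column score into the B-factors of all its atoms (sentinel −1 for
unmapped residues), the de-facto channel viewers color by.

## Assay arithmetic

Beer–Lambert (c = A/εl), occupancy (cofactor/protein molar ratio, > 1
flagged), NADH consumption rate (|dA340/dt|/εl and turnover per enzyme),
and single-point internal-standard correction (corrected =
measured/recovery). ε450(FAD) = 11300 M⁻¹cm⁻¹ and ε340(NADH) =
6220 M⁻¹cm⁻¹ ship as constants. All operations are homogeneous of degree 1
in their amount arguments, and the correction exactly inverts any
proportional loss — both property-tested.

## Synthetic fixtures

The generators produce inputs whose right answers are known in closed form,
which is what makes the test suite meaningful:

* **Tube ensembles**: carbon pseudo-atoms on a capped cylinder (atom spacing
  1.0 Å — tight enough that a 1.4 Å probe cannot leak between atoms), a
  constriction washer whose inner ring follows a per-frame radius schedule
  r(t), and two gate pseudo-residues placed diametrically on that ring so
  the choke diameter is exactly 2·r(t) − 2·r_vdW(C). Noise is applied to
  the ring radius, not per atom, so the analytic answer stays exact per
  frame. Radii are atom-center radii; the free (clearance) radius at the
  axis is r − 1.70 Å. Default study conditions: 12-frame ensembles, gate
  radius 4.0 Å (diameter ≈ 4.6 Å, an open channel breathing around the 4 Å
  threshold), ring noise sd 0.15 Å — chosen as a realistic ±0.3 Å
  thermal-fluctuation band for a side-chain-gated choke point.
* **Blocked variant**: identical topology, but the gates' Arg/Glu-like tips
  are placed 3.0 Å apart across the lumen in every frame — a persistent
  salt bridge, and a choke diameter that never opens. Tunnel-recovery runs
  use a wider tube (base 7.2 Å) and a 1.0 Å probe so that the smallest
  tested clearance (1.5 Å) stays passable after grid discretisation.
* **Reference sites**: classical multidimensional scaling embeds a target
  distance matrix exactly (residual < 1e-6 Å, infeasible matrices
  rejected); decoys ≥ 8 Å away exercise atom resolution.
* **MSAs**: per column, one dominant residue with probability p solved
  (Brent's method) so the expected normalized-entropy conservation equals
  the target; remaining mass uniform over the other 19 residues.

What the fixtures do *not* emulate: real protein packing, side-chain
rotamers, correlated frame-to-frame motion, solvent, or phylogenetic
structure in the MSAs. Passing tests therefore demonstrate that the
geometric and statistical machinery is correct, not that any particular
real enzyme's channel behaves a given way.

## Problem sizes and determinism

Default analysis sizes — 12-frame ensembles, ~1 200-atom tube frames,
0.5 Å grids, 100–200 oracle trials — keep every example and the full
reproduction script in the seconds-to-a-minute range on one CPU while
leaving the discretisation bounds testable; all generators and the
reproduction script take explicit seeds, and identical config + inputs
reproduce every numeric output exactly.

## Known limitations

* Tunnel search is grid-based: bottleneck radii carry an O(spacing) error
  and very narrow (< probe + spacing) passages can be missed; no
  Voronoi-exact geometry, no cross-frame tunnel clustering.
* The conservation score ignores phylogeny and substitution similarity.
* Exit classification assumes a roughly star-convex protein: the outward
  direction is taken from the atom centroid.
* PDB only (no mmCIF/DCD/XTC); the ensemble abstraction is the extension
  point.
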