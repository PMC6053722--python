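# Methods

This note records the models, parameter choices and numerical conventions
behind `rincompare`, and what the synthetic fixtures do and do not
demonstrate about real crystal structures.

## Structure model and PDB handling

Structures are parsed with gemmi into a plain chains → residues → atoms
model keyed by author (PDB) residue numbering, because the lysozyme
literature names residues by author numbers (21, 62, 104, 112–117, 122).
Ambiguities are resolved deterministically: only the first MODEL of a
multi-model file is read; waters are always dropped and other HETATM
residues dropped by default (retainable via `keep_hetatm=True`); within an
alternate-conformer group the highest-occupancy conformer wins, ties going
to the alphabetically first alt-loc. Hydrogens are retained when present,
but all geometry is computed over heavy atoms except the optional
hydrogen-bond donor-angle check — crystal structures at 1.3–1.8 Å
resolution generally lack hydrogens, so no analysis may depend on them.
Coordinates round-trip through the writer at the format's printed precision
(3 decimals; B-factors 2).

## Superposition and the displacement filter

A single least-squares rigid fit (Kabsch, computed via scipy's
`Rotation.align_vectors`) over **all** shared Cα atoms defines the
reference↔variant transform; per-residue RMSD is then taken over atoms
present under the same name in both partners ("all heavy atoms" by default;
`sidechain_only` and `ca_only` scopes available). Pairing is by identical
author number with no sequence alignment — the intended inputs are
identical-length point mutants.

The displacement threshold defaults to 1.9 Å, the convention of demanding a
displacement larger than the worst resolution of the compared structures
(≤ 1.8 Å for the lysozyme set); the rationale is carried as config metadata
and not enforced. The shared-displacement set is the intersection over
variants of {residue : RMSD ≥ threshold}, so raising the threshold can only
shrink it (a property test asserts this).

An optional iterative mode (`iterative_fit=True`) re-fits after dropping Cα
pairs deviating by more than 2.0 Å, up to 10 rounds, emulating
outlier-pruned superposition tools. The single-pass fit is the default:
with point mutants and a residue-level threshold the retained/discarded
decision is robust to the difference, but both modes are exposed because
marginal residues near 1.9 Å could in principle differ. Tests that plant an
exact displacement use the iterative mode so the fit is anchored by the
untouched majority and the planted magnitude is recovered exactly.

## Contact networks and MCODE

The residue-interaction network takes each residue's Cα as its node
(0-based indices, author numbers as labels) and joins every pair within the
cutoff, 7.0 Å by default and **inclusive** — "within" is read as ≤, a
measure-zero choice for real coordinates but fixed and configurable.
Sequence neighbors are included like any other pair.

MCODE is implemented from its published definition rather than wrapped,
since the algorithm is the analysis's core:

- vertex weight = k · density(H) where H is the highest k-core of the
  closed neighborhood N[v] and k its core number; weight 0 below the degree
  cutoff (2);
- seeds are visited by (weight desc, node id asc); breadth-first expansion
  admits unassigned neighbors with weight ≥ seed·(1 − node score cutoff),
  node score cutoff 0.2, depth-limited at 100; a vertex joins at most one
  cluster core;
- post-processing: clusters lacking a 2-core are dropped (k-core filter 2),
  optional fluff (off by default, boundary density cutoff 0.1), haircut (on)
  iteratively removes members with fewer than two within-cluster neighbors;
- cluster score = density × size with loop-less density 2E/(n(n−1)) — a
  6-residue clique scores exactly 6.00; clusters below the retention score
  are discarded, 5.00 by default and compared inclusively (≥), matching a
  published table in which a rank-4 cluster scores exactly 5.00;
- ranking is by (score desc, smallest member index asc). The published
  algorithm leaves seed and ranking ties open; both tie-breaks here are
  deterministic and documented so identical inputs give identical output.

The defaults (degree cutoff 2, node score cutoff 0.2, k-core filter 2,
max depth 100, haircut on, fluff off) are the defaults of the widely used
Cytoscape implementation, which the lysozyme analysis employed without
reporting settings. Equivalence with an independently written naive
implementation is asserted exhaustively on all labeled connected graphs up
to 5 nodes and on the complete graph atlas at 6–7 nodes, plus a seeded
sample of 8-node connected graphs; exhaustive isomorphism-free enumeration
at 8 nodes would require dedicated graph-generation tooling and adds little
beyond the sampled coverage.

Cross-structure cluster comparison matches each variant cluster to the
reference cluster of maximal Jaccard overlap (on author numbers), reports
gains/losses and score deltas, and flags residues whose membership changed
in **every** variant.

## B-factor statistics

A cluster's average B-factor is the unweighted mean over member residues of
each residue's atom-mean B ("average residue B-factor" names a per-residue
attribute averaged over a selection); the atom-pooled mean is available via
`pooled=True` and differs whenever residues have unequal atom counts. The
score/B-factor correlation is Pearson's r with the two-sided p from
t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom. By convention the
correlation uses the top four retained clusters of each structure (n = 12
for a three-structure study). Degenerate variance raises a "correlation
undefined" error rather than returning NaN. The t-based p is a continuous
approximation of the exchangeable null: against a 10⁶-draw permutation
estimate at n = 20 it agrees to within a few percent, which is the slack the
corresponding test allows on top of Monte-Carlo error.

## Interface energetics

Typed contacts are detected per residue pair from closest-atom geometry over
heavy atoms:

| type | rule | default threshold | default energy |
|------|------|-------------------|----------------|
| IONIC | opposite formal charges (Lys NZ; Arg NE/NH*; His ND1/NE2; vs Asp OD*; Glu OE*; C-terminal OXT) | 4.0 Å | 20 kJ/mol |
| HBOND | donor–acceptor heavy atoms, donor angle ≥ 90° when hydrogens exist | 3.5 Å | 17 kJ/mol |
| SSBOND | Cys SG–SG | 2.5 Å | 167 kJ/mol |
| PIPISTACK | ring centroids, normals parallel (≤ 30°) or T-shaped (≥ 60°) | 6.5 Å | 9.4 kJ/mol |
| PICATION | ring centroid to Lys NZ / Arg CZ, axis angle ≤ 45° | 5.0 Å | 9.6 kJ/mol |
| VDW | closest heavy atoms within radii sum + tolerance, only if no specific type fired for the pair | +0.5 Å | 6 kJ/mol |

The table lives on `InteractionConfig` as data, following the "strict"
conventions of standard residue-interaction-network generators; absolute
energy totals are meaningful only relative to a chosen table, which is why
the package's reproduction target for printed interface tables is their
internal percentage arithmetic, not the absolute counts and kJ/mol totals
(those additionally depend on a docking program's top-ranked poses).
Intra-chain pairs must be separated by more than two residues in sequence;
inter-chain pairs are exempt. One edge per (pair, type) is emitted with the
minimal qualifying distance; several types may fire for one pair (a salt
bridge typically also hydrogen-bonds), matching the multi-edge convention
of the tools this emulates.

Interprotein summaries count only inter-chain edges. Residues of interest
(default {21, 62, 104, 112–117, 122}) match by author number on either
endpoint by default — the stricter both-endpoints rule is implemented, but
interface figures in the motivating study highlight single side chains at
interfaces, making either-endpoint the natural reading. Percentages are
rounded half-up to one decimal, which reproduces every printed
residues-of-interest percentage of the published dimer/trimer tables from
their printed totals.

## Synthetic fixtures: what they show and what they don't

The generators emulate exactly the features each stage consumes: ideal
helices with the ~3.8 Å consecutive-Cα spacing of real helices and
controllable B-profiles; rigid per-residue perturbations with recorded
ground truth; template side chains (Lys/Arg/Glu/Cys/Ala) whose key atoms can
be placed to realize designed contact geometries within 0.05 Å; small
graphs with hand-traceable MCODE outcomes. All randomness is seeded and PDB
output is byte-deterministic.

They are not physically realistic proteins: no rotamers, no solvent, no
correlated backbone motion, pseudo side chains for most residues, and
perturbations that translate whole residues rather than repack them.
Passing planted-truth tests therefore demonstrates algorithmic correctness
(the pipeline recovers what was planted), not that the 1.9 Å/7 Å/5.00
defaults are optimal for any particular protein family. The
crystal-structure checks (shared displaced residues {21, 62, 104, 122},
the 112–117 cluster at 5.11 → 6.00, four retained clusters per monomer)
activate only when the real coordinate files are supplied under
`data/pdb/`, since they are not distributable and the pipeline never
fetches from the network.

## Problem sizes and numerics

Default test and acceptance runs use 30-residue helices, ≤ 20-node graph
fixtures, exhaustive graph enumeration to 7 nodes with 300–400 sampled
8-node graphs, 100 random rigid-fit instances, and one 10⁶-draw permutation
check — all chosen as the smallest sizes that make each property
non-trivial. Rigid fits are validated against an independent
quaternion-eigenvalue solver to 10⁻⁶ Å; rotations are checked orthonormal
to 10⁻⁸. Distance cutoffs are compared with ≤ throughout; KD-trees
accelerate contact searches without changing results. Percentages use
decimal half-up rounding, not banker's rounding, to mirror printed tables.

## Known limitations

- Residue pairing assumes identical author numbering (point mutants);
  non-isomorphic structures would need alignment-driven pairing, which is
  out of scope.
- The hydrogen-bond detector does not infer ideal hydrogen positions; in
  hydrogen-free crystal structures the donor-angle criterion is skipped and
  detection is purely distance-based.
- π-system detection uses ring-centroid geometry only (no multipole model).
- MCODE's published procedure leaves tie-breaking unspecified; other
  implementations may order equal-score clusters differently even though
  memberships agree.
- The interface energy table is empirical and configurable; totals are not
  force-field energies.
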