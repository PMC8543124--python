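# Methods

## Model

A structure is reduced to its residues and their heavy-atom coordinates.
The amino-acid network (AAN) at cutoff *c* links residues *i* and *j* when
some inter-residue atom pair is within *c* Å, with weight w_ij = the number
of such pairs; the comparison is **inclusive** (≤ c).  Node degree k_i
(residue neighbors) measures amino-acid packing, node weight
w_i = Σ_j w_ij (atomic contacts) measures atomic packing.  Profiles are
taken over the integer cutoffs 3–11 Å, which bracket the chemical
interaction threshold (~5 Å) and probe the space occupancy beyond it.
Because the edge set at a smaller cutoff is contained in the edge set at a
larger one, every profile is non-decreasing — a structural invariant the
test suite asserts on every fixture.

Sequence-adjacent (peptide-bonded) residues are **not** excluded: the link
definition is purely distance-based.  An `exclude_seq_adjacent` option
drops links between residues within a chosen sequence distance for
sensitivity analysis; it defaults to off.

## Plateau versus linear

With consecutive integer cutoffs the derivative of a degree profile is the
forward difference Δk(c) = k(c+1) − k(c).  A step is part of a plateau when

* Δk(c) = 0, or
* Δk(c) = 1 and the immediately preceding step Δk(c−1) ≥ 4 (default,
  `strict`): a burst of ≥ 4 new neighbors whose bulk then fills the next
  shell.

Consecutive plateau steps merge into segments [c_start, c_end]; a residue
with any segment is *plateau*, otherwise *linear* — the two labels
partition the residues, and the linear-fit R² is reported as a diagnostic
only, never used to gate the label.  The quantifier in "preceding step" is
genuinely ambiguous, so an `any-preceding` variant (any earlier step ≥ 4
licenses a unit step) is implemented behind the `plateau_rule` flag and
surfaced in the CLI and the acceptance policy grid.  Multiple disjoint
segments are all retained; the 1D barcode shows the first (lowest-cutoff)
segment, with the full list in the per-residue TSV/JSON exports.  An
all-zero profile (an isolated residue, possible only in artificial inputs)
is labeled plateau-degenerate and excluded from the census counts.

## Side-chain size classes

The three classes are fixed membership sets by extended side-chain length —
small < 3 Å {G, A, P, S, V, I, T, C}, medium 3–5 Å {L, E, D, H, N, Q, M},
big ≥ 5 Å {F, K, R, Y, W} — a disjoint cover of the 20 standard amino
acids.  They are looked up, never recomputed from coordinates.  The 2D
barcode divides each residue's neighbors at each cutoff among the classes
and stores percentages at full precision; zero-degree cells are all-zero
and flagged so matrices stay rectangular.  Neighbor percentages can be
computed over all chains (default; the bound ligand contributes neighbors)
or restricted to chosen chains.

## Atom selection policy

Crystal structures deposit no hydrogens and may carry alternate conformers,
waters, ions and modified residues.  Defaults: heavy atoms only (a flag
re-admits hydrogens), highest-occupancy altloc with ties broken by label
order, waters and non-amino-acid heteroatoms removed, first model of
multi-model files, all peptide chains kept.  Nonstandard residues are
skipped and recorded in provenance; an optional mapping (e.g. MSE→M)
re-admits them.  Short peptide chains (≤ 10 residues in a multi-chain
structure) are treated as the bound ligand; they are included by default —
both as rows and as neighbor contributors — and removable with
`include_ligand=False` / `--no-ligand`.  Whether published counts for the
case study include the ligand is not documented, so the census is always
computable under both settings.

## Numerical choices

* Distances are compared directly with no tolerance: coordinates carry the
  PDB's fixed 3-decimal precision, so exact-boundary cases are well
  defined, and the k-d-tree query (`scipy.spatial.cKDTree.query_pairs`) is
  inclusive like the link definition.  The tree is an implementation
  detail; the contract is brute-force enumeration of all atom pairs, and
  the test suite checks exact agreement of edges, weights and degrees
  against an independently written double loop.
* Profiles are computed from a single neighbor search at the maximum
  cutoff, binning each inter-residue atom-pair distance into the grid;
  equivalence with building every network independently is a tested
  invariant, not an assumption.
* R² = 1 − SS_res/SS_tot from an ordinary least-squares fit with
  intercept; a zero-variance response returns R² = 0 with a flag.
  Coefficients are reported in ascending powers.
* All exports are deterministic: fixed float formats, sorted JSON keys, no
  timestamps; the manifest records the full configuration and the input's
  SHA-256, so identical runs produce byte-identical tables.

## Synthetic data

The generator produces (a) explicit layouts — e.g. single-atom residues on
a line with chosen spacing — whose degrees at every cutoff are
hand-computable in closed form, and (b) random packed clusters: n residues
of a few atoms each placed uniformly in a box with a minimum atom
separation (defaults 10–30 residues, 3 atoms/residue, 15–22 Å box, 1.2 Å
separation), dense enough that the 3–11 Å grid yields rich, strictly
growing neighborhoods.  Generation is deterministic in (spec, seed) and
every structure round-trips through the PDB writer/parser.  Clusters
emulate the *density* of a folded core, not its chemistry: they have no
backbone connectivity, no secondary structure, no realistic side-chain
geometry, and uniform rather than residue-specific atom counts.  Passing
tests on them therefore establishes the correctness of the graph
construction, profile, classification and barcode machinery — not any
biological claim about real proteins, which requires running the pipeline
on deposited structures such as the PDZ case study (PDB 1BE9, fetched on
demand; see `data/README.md`).

## Problem sizes

The property suite uses 20 random clusters of 5–50 residues (1–4 atoms
each) for oracle comparisons, exhausts all monotone degree profiles of
length ≤ 6 with steps ≤ 4 (3 905 profiles) for the plateau rule, and
samples 500 longer profiles; the whole suite runs in a few seconds on one
CPU.

## Limitations

* Links are purely geometric; no decomposition into interaction types
  (hydrogen bond, hydrophobic, ...).
* Burial/surface assignment and secondary-structure breakdowns are out of
  scope, as are normal-mode or MD-based dynamics.
* The barcode representations describe one structure; cross-protein
  barcode comparison metrics and clustering of neighborhood classes are
  not implemented.
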