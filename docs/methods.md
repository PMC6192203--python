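# Methods

## Problem and model

pocketclique annotates a query protein structure by searching it for known
binding and catalytic sites.  A *site template* is the set of residues
(with coordinates) that surround a ligand in a holo structure, or the
catalytic residues of an enzyme.  Detection is formulated as rigid
sub-structure matching on an **association (product) graph**:

- every residue is reduced to two pseudo-atoms, the Cα position and the
  side-chain heavy-atom centroid (glycine degenerates to Cα alone);
- a graph vertex is a pair (template residue *i*, query residue *j*) whose
  amino-acid types are compatible;
- an edge joins vertices ((i,j),(k,l)) when i≠k, j≠l and the template-side
  and query-side pairwise distances agree within a tolerance `dist_tol`
  for **both** pseudo-atom types:
  |d_Cα(tᵢ,tₖ) − d_Cα(qⱼ,qₗ)| ≤ τ and |d_sc(tᵢ,tₖ) − d_sc(qⱼ,qₗ)| ≤ τ.

Any clique of this graph is an injective residue correspondence that is
pairwise-distance-consistent, i.e. a candidate rigid placement of the
template in the query.  Maximal cliques are enumerated exactly with
Bron–Kerbosch (pivot selection plus a degeneracy-ordered outer loop) over
bitset adjacency.  Each correspondence is then superposed by the Kabsch
algorithm (SVD with determinant sign correction, so reflections are never
returned) and scored.

The two-pseudo-atom residue representation is this package's own design:
it captures side-chain orientation, which matters for binding, without the
cost and fragility of full-atom matching.  Cα-only matching would accept
correspondences with incompatible side-chain geometry; full-atom matching
would require rotamer handling out of scope here.

## Composite score

Each hit is ranked by

    S = w_c · (clique_size / template_size) + w_r · exp(−RMSD / ρ) + w_l · rel_size

with defaults w_c = 1, w_r = 1, w_l = 0.5, ρ = 1.5 Å.  The three terms are
the fraction of the template recovered, an exponential reward for tight
superposition, and the relative size of the SMILES-similarity cluster
containing the template's ligand.  The rationale for the ligand term: a
template whose ligand belongs to a large family of chemically similar
ligands represents a recurring, biologically common binding chemistry, so
a geometric match to it is more credible than a match to a chemical
singleton.  The formula is a reconstruction: it is bounded
(S ∈ [0, w_c+w_r+w_l]), strictly increasing in clique size and cluster
size, strictly decreasing in RMSD, and every constant is exposed in
configuration so an alternative combination can be dropped in.  Catalytic
templates carry no ligand; their ligand term is zero and their score range
is [0, w_c+w_r].  Ties are broken deterministically by (RMSD ascending,
clique size descending, template id), so ranking is a total order and
shuffle-invariant.

The scan pipeline keeps each template's best-scoring record before the
final ranking: multiple overlapping cliques of one template are placements
of the same site, and reporting them as separate ranked hits would crowd
the top-k list with duplicates.

## Ligand clustering

Ligand SMILES are fingerprinted with Morgan circular fingerprints
(radius 2, 2048 bits) when rdkit is importable; otherwise with a hashed
character-3-gram fingerprint over the raw SMILES string (blake2b hash,
2048 bits).  The fallback does not canonicalize SMILES — two different
writings of one molecule may fingerprint apart — which is accepted as a
documented limitation; the backend in use is recorded in every output's
metadata.  Clustering is Taylor–Butina leader clustering at Tanimoto
≥ 0.7: ligands sorted by neighbour count (ties by code), densest
unassigned ligand becomes a centroid with its unassigned neighbours.
Butina was chosen because it is deterministic, threshold-driven and the
standard method for fingerprint clustering at library scale.
`rel_size` is normalized by the **largest** cluster (max weight exactly 1);
normalization by total ligand count is available behind
`cluster_norm = "total"`.

## Interface mode

By default the association graph is built for one query chain at a time,
so a correspondence never crosses chains.  With `interface_mode` the graph
is built over all chains jointly and a clique may span subunits — this is
how sites hosted at the interface between chains are detected.  Per-chain
mode remains the default because joint graphs are larger (slower, more
chance matches) and most sites are intra-chain.

## Tunable parameters

| parameter | default | unit | role |
|---|---|---|---|
| `dist_tol` | 1.5 | Å | pairwise-distance agreement for graph edges |
| `min_clique_size` | 3 | residues | smallest reported correspondence (3 is the minimum that constrains a rigid transform) |
| `rmsd_cutoff` | 3.0 | Å | discard poor superpositions |
| `contact_cutoff` | 4.5 | Å | heavy-atom distance defining template contact residues (standard contact definition) |
| `aa_mode` | strict | — | residue compatibility; `relaxed` groups {DE},{KRH},{ST},{ILVM},{FYW},{NQ},{AG},{C},{P} |
| `sim_threshold` | 0.7 | Tanimoto | Butina clustering threshold |
| `w_clique, w_rmsd, w_ligand, rmsd_scale` | 1, 1, 0.5, 1.5 Å | — | composite score |
| `edge_budget` | 200 000 | edges | graphs above this are skipped loudly, never truncated |
| `max_cliques` | 100 | cliques | per-graph result cap (after deterministic sorting) |

The geometric defaults (`dist_tol`, `min_clique_size`, `rmsd_cutoff`) are
deliberately permissive at template scale (sites of 3–20 residues) and are
all configurable; none is claimed to be optimal.  Clique enumeration is
worst-case exponential, so the edge budget makes the failure mode explicit:
a template whose graph exceeds it is reported as skipped in the report
footer rather than searched partially.

## Synthetic-data generator

The generator emulates the apo/holo asymmetry of binding-site benchmarks.
A planted site is `n` residues (default 5–8) placed by rejection sampling
in an 8 Å sphere with pairwise Cα separation ≥ 3.2 Å; side-chain centroids
sit at a fixed 1.5 Å offset in a random direction.  The unperturbed copy
becomes the template; a copy with i.i.d. Gaussian coordinate noise
(default σ = 0.3 Å, a typical apo-vs-holo side-chain-scale perturbation)
plus 50 decoy residues in a 20 Å sphere becomes the query.  Decoy template
libraries hold 50 random geometric templates of 4–8 residues with ligands
drawn from a built-in pool of 20 valid SMILES.  Chain-split benchmarks
partition the 5 site residues 3+2 over two chains.

What the generator does **not** emulate: polymer connectivity, secondary
structure, realistic packing density, side-chain rotamers, or conformational
change between apo and holo beyond isotropic noise.  Passing the planted-site
benchmarks therefore demonstrates the correctness and discriminative power
of the matching/scoring machinery under controlled geometry — not predictive
performance on real apoproteins, which depends on a PDB-scale template
database outside this package's scope.

All randomness flows through numpy's PCG64 generator; the same seed gives
byte-identical PDB/library files on any platform.

## Numerical choices

- Kabsch RMSD is computed over the stacked pseudo-atoms of matched
  residues only (glycine contributes a single point, never a duplicated
  Cα); negative round-off under the square root is clamped to zero.
- Generated coordinates are rounded to 1e-3 Å (PDB precision) *before*
  template construction, so a noiseless self-match is exact rather than
  bounded by the file format.
- Clique output ordering, residue ordering, JSON key ordering and float
  formatting are all fixed, making every output byte-reproducible; the
  report embeds tool version, config hash, library format version and
  fingerprint backend.
- Altloc handling keeps, per atom name, the highest-occupancy conformer
  (ties: first in file).  MSE is remapped to MET; other non-standard
  residues are dropped with a warning.

## Benchmark problem sizes

The shipped benchmarks use 100 recovery trials (51-template libraries,
~55-residue queries), 20 interface trials, 200 clique-oracle graphs of
≤15 vertices, and 1000-point score sweeps.  These sizes make every oracle
comparison exhaustive and keep the full suite fast enough to run on every
change; the engine itself has no size assumptions beyond the edge budget.

## Known limitations

- No statistical significance (e-value) for scores; ranks are only
  comparable within one scan.
- Strict residue matching misses sites conserved through substitutions;
  `relaxed` mode is a coarse remedy, not a substitution matrix.
- The exact-clique strategy with an edge budget refuses (rather than
  approximates) very large or low-complexity graphs.
- One model per structure; NMR ensembles and altloc ensembles beyond
  best-occupancy are not modelled.
- The k-gram fingerprint fallback is string-based chemistry: adequate for
  grouping identical/near-identical SMILES, not for true chemical
  similarity.
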