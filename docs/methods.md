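# Methods

## Graph construction

Each polymer residue of the input structure becomes one node, positioned
at its Cα (amino acids) or P (nucleotides). Two residues are connected
when any pair of their heavy atoms lies within the contact cutoff
(default 4.5 Å, the conventional range capturing van der Waals and
electrostatic interactions in residue-network studies). The edge is
weighted by the local interaction strength

    a_ij = N_ij / (N_i · N_j)

where N_ij is the atom–atom contact count and N_i, N_j the residues' heavy
atom counts; edge length is 1/a_ij. The denominator removes the packing
bias between small amino acids and large nucleotides; without it,
nucleotides would dominate purely by size. A √(N_i·N_j) denominator is
selectable (`normalization="sqrt_product"`) because both size-normalisation
conventions appear in the residue-network literature; all downstream code
is agnostic to the choice and every output file records the mode used. The
closeness magnitudes produced by the product form (~10⁻⁶ on a ~10⁴-node
complex) are what the default reporting assumes.

Decisions a user should know about:

- **Closed cutoff.** The distance test is `d ≤ cutoff`. The k-d tree query
  (`scipy.spatial.cKDTree.query_pairs`) uses the same closed interval, and
  the brute-force reference (`count_contacts_bruteforce`) is shipped so the
  equivalence is testable on any structure.
- **No sequence-neighbour exclusion.** Covalently bonded neighbours are
  linked through their atom contacts exactly like long-range pairs; bonded
  and nonbonded edges are only told apart in the summary histograms.
- **min_contacts = 1.** Any atom pair within the cutoff creates an edge;
  the threshold is configurable.
- **Atom selection.** Hydrogens are dropped (≈3 Å crystal structures carry
  none, so N_i counts the heavy atoms actually present). Of altloc groups,
  the highest-occupancy conformer is kept, ties broken by altloc letter.
  Waters, ions and non-polymer ligands are excluded; modified polymer
  residues (HETATM inside a polymer chain) are retained and classified by
  chemical identity or, failing that, by the presence of a P (nucleotide)
  or Cα (amino acid).
- **Missing representative atoms.** A residue lacking its Cα/P (typically
  a 5′-terminal nucleotide without phosphate) is kept with the centroid of
  its atoms as node position and a `rep_fallback` flag; dropping such
  residues is available via `on_missing_rep="drop"`. Dropping silently
  would delete the first residue of many RNA chains.
- **Model 1 only**; residue numbers are taken verbatim from the file
  (author numbering), since functional sites are cited that way (A2451,
  G530, ...).

## Centralities

Degree is the incident-edge count. Closeness is CC(l) = N / Σ_j d_lj with
N the node count of the graph; the conventional N−1 numerator is available
behind a flag (only relative orderings change). Betweenness is the
endpoint-excluded pair-normalised form, CB(l) ∈ [0, 1], computed by a
tie-tolerant Dijkstra census with Brandes-style dependency accumulation.

Numerical choices:

- **Tie tolerance.** Shortest-path counts σ over real-valued 1/a_ij
  lengths use a relative tolerance ε = 10⁻⁹ when recognising equally short
  routes, making σ reproducible across platforms. Exact ties (unit-weight
  test graphs) are recognised exactly.
- **Determinism.** Nodes are settled in (distance, index) heap order and
  accumulated in a fixed order; repeated runs are bit-identical.
- **Disconnected graphs** raise an error naming the component sizes, since
  closeness over a disconnected graph is meaningless; `per_component=True`
  computes closeness with N = component size and betweenness normalised by
  each component's pair count. Ribosomal networks are expected connected;
  stray ligand chains would otherwise distort closeness silently.
- The implementation's contract is equality (10⁻¹⁰) with exhaustive
  shortest-path enumeration, which the test suite enforces on every graph
  ≤ 40 nodes it uses, alongside an independent networkx cross-check.

The betweenness normalisation convention matters for absolute thresholds:
a published top-quantile cut such as 0.013 is only meaningful under the
convention that produced it, so the reporting layers treat hub membership
(rank-based) as primary and the absolute threshold as informational.

## Hubs, pathways and reports

Hub extraction takes the q-quantile (default 0.95) of the betweenness
distribution using the linear-interpolation quantile estimator and keeps
nodes with CB ≥ threshold, so tied scores at the cut are all included; an
all-equal distribution triggers a degenerate-distribution warning. Hub
pathways are the connected components of the full network's edge set
restricted to hub nodes — adjacency is *not* recomputed at a different
cutoff, because the question is whether hubs sit next to each other in the
existing contact topology. Component statistics group nodes by annotation
category into amino acid (r-proteins), rRNA (16S+23S+5S), tRNA, mRNA and
factor classes; the groups partition the annotated nodes, so group means
recombine exactly to the grand mean. Site and bridge definitions are
editable YAML shipped with the package (DC, PTC, bridges B1b–B8 in
T. thermophilus author numbering); selectors are resolved against chain
IDs first, then against annotation molecule names.

## Synthetic fixtures

The generators emulate desk-scale structures whose contact topology is
known analytically, so every pipeline stage is testable without large
inputs:

- **linear_polymer** — residue clusters spaced at 0.8×cutoff along a line;
  the network is exactly the path graph P_n.
- **star** — a hub residue with one arm pseudo-atom per satellite
  (satellites on a Fibonacci sphere); the network is exactly K_{1,n−1}.
  The arm construction exists because a bare single-atom hub cannot keep
  satellites mutually separated at ≥1.3×cutoff for n ≥ 6.
- **two_domain_bridge** — two contact cliques (anchor + tight cluster)
  joined only through one bridging residue; all inter-domain shortest
  paths run anchor → bridge → anchor, making the bridge the strict global
  betweenness maximum and the unique articulation point. One chain is
  protein, the other RNA pseudo-nucleotides, exercising the component
  grouping. Clique domains (rather than loosely packed grids) are used
  deliberately: in a non-clique domain the residue adjacent to the bridge
  can accumulate more betweenness than the bridge itself.
- **random_geometric** — residues uniform in a box sized so the expected
  mean degree hits a target (default 8.5, a typical dense-packing value
  for intact ribonucleoprotein complexes). The box size is solved from a
  fixed-seed quasi-random estimate of the contact probability that models
  the actual atom clusters, so the realised mean degree is unbiased; the
  declared tolerance (±20 %) covers finite-size fluctuation. Used for
  oracle-equivalence tests and the acceptance script.

Intended contacts are placed at 0.8×cutoff and intended non-contacts at
≥1.3×cutoff, and every generator verifies its declared topology by brute
force before returning. The fixtures reproduce contact *topology* only —
no physically meaningful conformations, B-factors, or base geometry — so
passing tests demonstrate correctness of graph construction, centrality
computation and reporting, not agreement with any particular crystal
structure. Statements about real 70S complexes are checked separately by
the acceptance-level tests, which require the deposited coordinate files
to be supplied by the user (no download client is included).

## Problem sizes

The test suite and `scripts/acceptance.py` run on fixtures of 7–200
residues: enumeration oracles are exponential in path multiplicity and are
applied to graphs ≤ 40 nodes; the 200-residue random-geometric fixture
exercises the k-d tree path and quantile machinery at a size where the
full table computes in well under a second. A full 70S complex (~11000
nodes, ~5·10⁴ edges) runs through the same code; the all-sources
betweenness pass is the dominant cost there (hours on one CPU with this
pure-Python engine).

## Known limitations

- The annotation templates for the four study entry pairs follow the
  depositions' conventional chain naming and must be verified against the
  actual files by the user.
- Per-component closeness uses component size as the numerator; comparing
  closeness across components of very different sizes is not meaningful.
- The centrality engine is exact but not parallel; for repeated scans of
  large complexes an approximate/sampled betweenness would be the natural
  extension.
- Quantile thresholds and any absolute betweenness values depend on the
  normalisation conventions documented above.
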