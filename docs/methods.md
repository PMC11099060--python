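# Methods

## Problem and model

The package quantifies whether curated groups of disease genes — here the
distal-onset-only, proximal-onset-only and common-onset muscular-dystrophy
(MD) groups — occupy distinct regions of a multiplex molecular network, and
whether the common group behaves as a functional bridge.  Three instruments
are combined: group-wise shortest-distance statistics with random-gene-set
nulls, random-walk-with-restart (RWR) network neighborhoods with
label-permutation overlap tests, and hypergeometric over-representation
analysis.

## Curation

Candidate gene lists (one per onset) are filtered by gene–disease evidence
classifications: a candidate is retained when at least one assertion matches
the onset with a Moderate, Strong or Definitive classification, or when it
is explicitly whitelisted on literature support (CRYAB, MATR3, MYOT in the
shipped lists).  Conflicting assertions for the same gene are not
reconciled: any qualifying record suffices.  This is a deliberate
implementation choice — resolving conflicts would require a disease-ontology
match that the input format does not carry.  Symbols are canonicalized to
uppercase; no alias resolution is attempted, so inputs must carry final
symbols.  The onset-group split is pure set algebra: distal-only = D \ P,
proximal-only = P \ D, common = D ∩ P.

## Multiplex network

Layers are simple, undirected, unweighted graphs (weights in input files are
ignored with a warning) over the union of all endpoints.  Connectivity for
the largest connected component (LCC) is evaluated on the *aggregated* graph
(union of layer edge sets): a walker that can switch layers at any node
reaches exactly the aggregated component, so this is the universe on which
multiplex RWR and distances are well defined.  Per-layer connectivity is
deliberately not required; a gene may be isolated within any single layer.
Closeness centrality uses the per-component convention — the reciprocal of
the mean shortest-path distance to the other members of the node's own
component, 0 for isolated nodes — matching the NetworkAnalyzer convention
rather than the Wasserman–Faust rescaling.

## Distance statistics

The distance between gene sets A and B is the mean of d(a, b) over all
pairs with a ≠ b (for A = B this equals the mean over unordered distinct
pairs), so the statistic is symmetric and bounded by 1 from below and the
component diameter from above.  This is a mean over *all* pairs, not the
mean-of-minima separation used elsewhere in network medicine; the choice
follows the plain reading of "average shortest distances between genes" and
matters when comparing to published tables.

The null randomizes one side: `n_random` (default 2000) gene sets of exactly
|B| genes are drawn uniformly without replacement from the LCC node
universe, with no degree matching, and

    p = #{ d(A, random) < d(A, B) } / n_random .

The comparison is strict by default (a ≤ variant is config-exposed), and the
construction is directional; for inter-group pairs both directions are
reported, and intra-group cells are assessed with the same construction
(second argument randomized at size |A|).  Random sets may intersect A; when
they do, the coinciding gene contributes no pair (self-pairs are excluded,
exactly as in the statistic itself), which keeps the statistic ≥ 1 and makes
the complete-graph null degenerate at its floor.  A draw with no valid pair
at all — possible only for a singleton query drawn as its own random set —
is redrawn.  Singleton intra-group cells are reported as NaN (no distinct
pair exists).  In the summary table the per-group "Random" baseline uses
size-matched random sets; the random-vs-random cell uses the rounded mean
group size on both sides.

## Multiplex random walk with restart

States are (gene, layer) pairs.  From (v, l) the walker relocates to
another layer's copy of v with probability δ (`interlayer_jump`, default
0.5, split uniformly over the other layers) and otherwise steps to a uniform
within-layer neighbor.  A gene isolated in its current layer can only
relocate; a gene isolated in every layer (impossible inside the LCC) sends
the walker back to the restart distribution.  The restart vector is uniform
over seed genes × layers, and the stationary distribution solves
p = r·s + (1−r)·T·p with restart r (default 0.7).  With one layer, δ is
irrelevant and the walk reduces exactly to standard RWR.  Note that
duplicating a layer is *not* a no-op: relocation to the same gene in the
duplicate layer adds stay-put mass, which is the expected multiplex
semantics.

The fixed point is found by power iteration; the map is a contraction with
factor (1−r), so the default tolerance (L1 change < 1e-10) is reached in a
few dozen iterations.  Non-convergence within `max_iter` is flagged on the
result rather than raised.  Per-gene scores are the mean over layer copies,
renormalized to sum to one (rank-equivalent to the sum).  Neighborhoods are
the top-k genes by score *excluding the run's own seeds* (other groups' seed
genes may appear, which is required for cross-group containment to be
expressible), with lexicographic tie-breaking for determinism.  The supra
transition matrix is built once per network and reused across seed sets,
which makes thousand-permutation overlap tests cheap.

## Overlap significance

The statistic is the raw intersection size of two top-k neighborhoods (not
Jaccard).  Under the null all group labels are permuted jointly over the
network-present labeled genes (genes outside the network cannot seed a walk
and are excluded first), preserving group sizes by construction; both
neighborhoods are recomputed per permutation and

    p_low = #{ overlap_null ≤ overlap_real } / n_rand .

Small p_low means the real neighborhoods share *fewer* genes than
label-exchangeable ones.  Because overlaps are small integers with heavy
ties and ties count toward p_low, the test is conservative under the null.

## Enrichment

Standard hypergeometric over-representation: for a query of n annotated
genes, a term with K annotated genes and a background of N, the p-value is
the upper tail P(X ≥ k).  The background defaults to the union of all term
gene sets ("only annotated genes" domain scope) and can be overridden.
Multiple testing uses Benjamini–Hochberg at α = 0.05 across the tested
(overlapping) terms.  This is a deliberate substitution for the
tiered-threshold correction used by some web services, whose algorithm is
not fully public; adjusted p-values are therefore not expected to match
such services numerically, only the ranking logic.

## Synthetic benchmark

Each layer is an independent draw with the same block structure over a
shared universe of `n_genes` (default 300): Bernoulli(p_inter = 0.01) edges
everywhere, plus Bernoulli(p_intra = 0.15) edges inside each of two
communities (default 60 + 60).  Planted groups default to 11/22/7, mirroring
the real onset-group sizes: the distal-like group is sampled inside
community 1, the proximal-like group inside community 2, and the common-like
bridge group is drawn from the background, wired internally at p_intra (a
small dense cluster) and attached into each community with probability
`bridge_attachment` = 0.3 per layer and community (when attached, it links
to members at p_intra, at least one).  The internal bridge wiring and the
dual attachment give the bridge group the multifunctional phenotype the
analysis should detect: cohesive, straddling both modules, and annotated
with *both* community terms in the generated GMT (the noise terms are
uniform random gene sets).  Setting p_intra = p_inter collapses the
communities and serves as the negative control.

What the generator does not emulate: scale-free degree heterogeneity, layer
size asymmetry, correlated layers, and annotation hierarchies.  Passing
tests on this benchmark therefore demonstrate correctness of the machinery
and sensitivity to planted modular structure at these densities — not
performance on real interactome topology.

## Numerical choices and problem sizes

* RWR: tol 1e-10 (L1), max 1000 iterations; agreement with a dense
  closed-form solve is verified to < 1e-8 per gene on random multiplexes of
  up to 30 genes × 3 layers.
* Distances: integer BFS on the aggregated graph; cached distance rows make
  2000-set nulls an indexing exercise.
* Ties: neighborhood ranking breaks score ties lexicographically; LCC ties
  go to the component containing the lexicographically smallest gene.
* Seeds: a single global seed derives per-stage seeds by hashing the stage
  name (all below 2^31), so full runs and standalone stages reproduce
  byte-identical outputs.
* Suite-scale experiments use 20 synthetic bundles at generator defaults
  with 200 permutations / 200 random sets per bundle, and 200 calibration
  repetitions at 500 random sets each; the analysis drivers use the full
  2000-set / 1000-permutation settings.

## Known limitations

* The "any qualifying record" curation rule can keep a gene whose strongest
  assertion elsewhere is Disputed.
* Distances use the all-pairs mean; results are not comparable to
  mean-of-minima module-separation scores.
* Random-set nulls are not degree-matched; on degree-heterogeneous networks
  the null is liberal for hub-rich groups.
* The permutation universe for overlap tests is the network-present labeled
  genes; significance is conditional on that universe.
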