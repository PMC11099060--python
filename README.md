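# onsetnet

Systems-biology analysis of how disease-gene groups sit in a multiplex
molecular network, built around the muscular dystrophies (MDs).  MDs are
inherited muscle-wasting diseases whose initial weakness is either *distal*
(hands/feet) or *proximal* (limb-girdle).  Curated MD genes split into three
onset groups — distal-only (DoGs), proximal-only (PoGs) and common to both
onsets (CoGs) — and the package asks, quantitatively, whether these groups
occupy distinct functional neighborhoods of the interactome.

The package provides, as a reusable library plus numbered analysis drivers:

* **Curation** (`onsetnet.gene_sets`): evidence-level filtering of candidate
  gene lists (Moderate/Strong/Definitive assertions, plus a literature
  whitelist) and the three-way onset-group split.  The curated 40 MD genes
  (11 DoGs, 22 PoGs, 7 CoGs) ship with the package.
* **Multiplex assembly** (`onsetnet.multiplex`): named interaction layers
  (PPI, complexes, pathways) over a shared gene universe, aggregation with
  edge provenance, largest-connected-component extraction, induced
  subnetworks, closeness centrality, GraphML/SIF export.
* **Distance statistics** (`onsetnet.distances`): the mean shortest-path
  distance between gene sets,

      d(A, B) = mean over pairs (a, b), a in A, b in B, a != b of d_G(a, b),

  with an empirical bootstrap null — the randomized side is replaced by
  `n_random` uniform gene sets of equal size and `p = #{d_null < d_real} /
  n_random`.  The assessment is directional (randomizing B around A is not
  the same null as randomizing A around B).
* **Multiplex random walk with restart** (`onsetnet.rwr`): the walker moves
  on (gene, layer) states, switching layers with probability δ and walking
  within-layer otherwise, restarting at the seed group with probability
  r = 0.7; solves p = r·s + (1−r)·T·p.  The top-k non-seed genes by score
  form a group's *network neighborhood*.
* **Overlap significance** (`onsetnet.overlap`): the intersection of two
  groups' neighborhoods, tested by jointly permuting all group labels and
  recomputing both walks (`p_low` = fraction of permutations with overlap ≤
  the real one).
* **Enrichment** (`onsetnet.enrichment`): hypergeometric over-representation
  against GMT annotation collections with Benjamini–Hochberg correction.
* **Synthetic benchmark** (`onsetnet.synthetic`): a planted-partition
  multiplex with two dense communities, a distal-like group inside one, a
  proximal-like group inside the other, and a common-like bridge cluster
  wired into both and annotated with both community terms — so the whole
  pipeline is exercisable and testable without any downloads.
* **Pipeline** (`onsetnet.pipeline`): `run_pipeline` chains every stage
  deterministically from one seed and writes a manifest.

## Worked example

Running the numbered drivers in order (each is a thin script over the
library; outputs land under `results/`):

```sh
python analysis/01_curate_onset_groups.py
python analysis/02_simulate_multiplex.py
python analysis/03_network_topology.py
python analysis/04_group_distances.py
python analysis/05_rwr_neighborhoods.py
python analysis/06_functional_enrichment.py
```

prints, among other things:

```
40 muscular-dystrophy genes assigned: 11 distal-only, 22 proximal-only, 7 common
common genes: ANO5, CAV3, DES, DNAJB6, DYSF, MYOT, TTN

synthetic bundle (seed 42): 300 genes, layers {'ppi': 987, 'complexes': 1026, 'pathways': 1023}

mean shortest distances (groups + size-matched random baselines):
               distal_like  proximal_like  common_like  Random
distal_like            1.6           2.07         1.91    2.16
proximal_like          NaN           1.58         2.25    2.12
common_like            NaN            NaN         1.81    2.40
Random                 NaN            NaN          NaN    2.38

distal-like vs proximal-like top-50 overlap = 5; fraction of 1000 label
permutations with overlap <= real: p_low = 0.000

distal_like: 1 significant term(s): sarcomere_like (p_adj=6.52e-06)
proximal_like: 1 significant term(s): sarcolemma_like (p_adj=4.47e-12)
common_like: 2 significant term(s): sarcolemma_like (p_adj=6.09e-04), sarcomere_like (p_adj=6.09e-04)
```

Reading: every planted group is tighter-knit than its size-matched random
baseline (diagonal vs `Random` column); the distal-like and proximal-like
neighborhoods share far fewer genes than label-permuted controls
(`p_low = 0.000`); and enrichment recovers each single-community group's own
localization term while the bridge group — the analogue of the
both-onsets genes — is significant for *both* terms.

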