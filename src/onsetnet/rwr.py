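"""Random walk with restart on a multiplex network.

The walker lives on the supra-graph whose states are (gene, layer) pairs.
At each step, from state (v, l), it either keeps walking within layer l —
moving to a uniformly chosen neighbor of v in that layer, with probability
(1 - interlayer_jump) — or relocates to the copy of v in another layer,
chosen uniformly among the other layers, with probability interlayer_jump.
A gene isolated within its current layer can only relocate; a gene isolated
in every layer (impossible inside a largest connected component, but possible
on custom inputs) makes the walker restart from the seed distribution.

With restart probability r the stationary distribution solves

    p = r * s + (1 - r) * T p,

where s is uniform over the seed genes' copies across all layers and T is the
column-stochastic supra-transition described above.  The fixed point is
reached by power iteration (the map is a contraction with factor 1 - r).
Per-gene scores are the mean of the gene's layer-copy probabilities,
renormalized to sum to one; the network neighborhood of a seed group is the
top-k non-seed genes by score, ties broken lexicographically.

A single-layer multiplex degenerates to the standard random walk with restart
on that graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import sparse

from .multiplex import MultiplexNetwork

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RWRConfig:
    restart: float = 0.7
    interlayer_jump: float = 0.5
    tol: float = 1e-10
    max_iter: int = 1000
    aggregation: str = "mean_over_layers"

    def __post_init__(self) -> None:
        if not (0.0 < self.restart <= 1.0):
            raise ValueError("restart must be in (0, 1]")
        if not (0.0 <= self.interlayer_jump <= 1.0):
            raise ValueError("interlayer_jump must be in [0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.aggregation != "mean_over_layers":
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


@dataclass(frozen=True)
class ScoreVector:
    """Per-gene visitation probabilities for one seed set."""

    scores: dict
    seeds: frozenset
    converged: bool
    iterations: int

    def ranked_non_seeds(self) -> list:
        """Non-seed genes by descending score; ties broken lexicographically."""
        return sorted(
            (g for g in self.scores if g not in self.seeds),
            key=lambda g: (-self.scores[g], g),
        )


@dataclass(frozen=True)
class Neighborhood:
    """Top-k non-seed genes around a seed group, in rank order."""

    genes: tuple
    k: int
    seed_group: str = ""

    @property
    def gene_set(self) -> frozenset:
        return frozenset(self.genes)


class SupraWalker:
    """Reusable supra-transition operator for one multiplex network.

    Building the transition matrix dominates the cost of a single walk, so a
    walker is constructed once per network and queried for many seed sets
    (label-randomization tests run thousands of walks on the same network).
    """

    def __init__(self, mx: MultiplexNetwork, cfg: RWRConfig = RWRConfig()):
        self.cfg = cfg
        self.nodes = sorted(mx.nodes)
        self.node_index = {n: i for i, n in enumerate(self.nodes)}
        self.n_nodes = len(self.nodes)
        self.n_layers = len(mx.layers)
        self._T = self._build_transition(mx)

    def _build_transition(self, mx: MultiplexNetwork) -> sparse.csr_matrix:
        n, L = self.n_nodes, self.n_layers
        delta = self.cfg.interlayer_jump if L > 1 else 0.0
        rows, cols, vals = [], [], []
        graphs = mx.layer_graphs()
        for l, g in enumerate(graphs):
            for v in self.nodes:
                vi = self.node_index[v]
                col = l * n + vi
                nbrs = sorted(g.adj[v])
                walk_mass = 1.0 - delta if nbrs else 0.0
                jump_mass = delta if nbrs else (1.0 if L > 1 else 0.0)
                if nbrs:
                    w = walk_mass / len(nbrs)
                    for u in nbrs:
                        rows.append(l * n + self.node_index[u])
                        cols.append(col)
                        vals.append(w)
                if L > 1 and jump_mass > 0.0:
                    w = jump_mass / (L - 1)
                    for l2 in range(L):
                        if l2 == l:
                            continue
                        rows.append(l2 * n + vi)
                        cols.append(col)
                        vals.append(w)
                # genes isolated in every layer leave a zero column: the lost
                # mass is routed back to the restart distribution at iteration
                # time (the walker restarts).
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(n * L, n * L), dtype=float
        )

    def restart_vector(self, seeds: Iterable[str]) -> np.ndarray:
        seeds = sorted(seeds)
        s = np.zeros(self.n_nodes * self.n_layers)
        w = 1.0 / (len(seeds) * self.n_layers)
        for l in range(self.n_layers):
            for g in seeds:
                s[l * self.n_nodes + self.node_index[g]] = w
        return s

    def scores(self, seeds: Iterable[str]) -> ScoreVector:
        """Stationary distribution for one seed set, aggregated per gene."""
        seeds = frozenset(seeds)
        unknown = seeds - set(self.node_index)
        if unknown:
            raise ValueError(f"seed gene(s) not in network: {sorted(unknown)}")
        if not seeds:
            raise ValueError("empty seed set")
        r = self.cfg.restart
        s = self.restart_vector(seeds)
        p = s.copy()
        converged = False
        iterations = 0
        for iterations in range(1, self.cfg.max_iter + 1):
            tp = self._T @ p
            lost = 1.0 - tp.sum()  # mass absorbed by fully isolated genes
            p_next = r * s + (1.0 - r) * (tp + lost * s)
            delta = float(np.abs(p_next - p).sum())
            p = p_next
            if delta < self.cfg.tol:
                converged = True
                break
        if not converged:
            log.warning("RWR did not converge in %d iterations", self.cfg.max_iter)
        per_gene = p.reshape(self.n_layers, self.n_nodes).mean(axis=0)
        per_gene = per_gene / per_gene.sum()
        return ScoreVector(
            scores={g: float(per_gene[i]) for i, g in enumerate(self.nodes)},
            seeds=seeds,
            converged=converged,
            iterations=iterations,
        )


def rwr_multiplex(
    mx: MultiplexNetwork, seeds: Iterable[str], cfg: RWRConfig = RWRConfig()
) -> ScoreVector:
    """One random walk with restart from ``seeds`` on ``mx``.

    Seeds absent from the network are reported and dropped; an entirely
    absent seed set is an error.
    """
    seeds = frozenset(seeds)
    present = seeds & mx.nodes
    dropped = seeds - present
    if dropped:
        log.warning(
            "%d seed(s) not in network, dropped: %s", len(dropped), ", ".join(sorted(dropped))
        )
    if not present:
        raise ValueError("no seed gene is present in the network")
    return SupraWalker(mx, cfg).scores(present)


def extract_neighborhood(sv: ScoreVector, k: int = 50, seed_group: str = "") -> Neighborhood:
    """Top-k non-seed genes by score (deterministic lexicographic tie-break)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sv.ranked_non_seeds()
    return Neighborhood(genes=tuple(ranked[:k]), k=k, seed_group=seed_group)


def score_table(sv: ScoreVector):
    """Full score table as a DataFrame (gene, score, is_seed, rank among non-seeds)."""
    import pandas as pd

    ranked = sv.ranked_non_seeds()
    rank = {g: i + 1 for i, g in enumerate(ranked)}
    rows = [
        {
            "gene": g,
            "score": sv.scores[g],
            "is_seed": g in sv.seeds,
            "rank": rank.get(g, 0),
        }
        for g in sorted(sv.scores, key=lambda g: (-sv.scores[g], g))
    ]
    return pd.DataFrame(rows)
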