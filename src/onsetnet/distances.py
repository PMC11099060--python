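"""Group-wise average shortest distances and their bootstrap significance.

The statistic between two gene sets A and B is the mean shortest-path length
d(a, b) over all pairs a in A, b in B with a != b, computed on the aggregated
(union-of-layers) unweighted graph.  For A == B this equals the mean over
unordered distinct pairs; the statistic is symmetric in its arguments.

Significance is assessed against a random-gene-set null: the side B is
replaced by ``n_random`` uniform draws (without replacement, from the full
node universe of the network — by construction its largest connected
component) of the same size as B, and the empirical p-value is the fraction
of null distances strictly smaller than the observed one.  The construction
is directional: randomizing B around a fixed A and randomizing A around a
fixed B are different nulls and both are reported for inter-group pairs.

No degree matching is applied to the random sets and they may intersect A;
both choices are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .multiplex import AggregatedNetwork


@dataclass(frozen=True)
class NullConfig:
    """Random-gene-set null configuration.

    ``strict_less`` selects the comparison used for the empirical p-value
    (strictly smaller by default); ``exclude_query`` removes the fixed side's
    genes from the sampling universe (off by default).
    """

    n_random: int = 2000
    rng_seed: int = 42
    strict_less: bool = True
    exclude_query: bool = False

    def __post_init__(self) -> None:
        if self.n_random < 1:
            raise ValueError("n_random must be >= 1")


@dataclass(frozen=True)
class EmpiricalResult:
    p: float
    real_distance: float
    null_distances: np.ndarray


@dataclass(frozen=True)
class DistanceTable:
    """Table of group distances with directional empirical p-values."""

    mean_distance: dict          # frozenset({labelA, labelB}) -> float (symmetric)
    p_empirical: dict            # (fixed label, randomized label) -> float
    n_random: int
    rng_seed: int
    labels: tuple

    def to_matrix(self) -> pd.DataFrame:
        """Square matrix of mean distances in label order (upper triangle filled)."""
        labels = self.labels
        mat = pd.DataFrame(np.nan, index=labels, columns=labels)
        for i, la in enumerate(labels):
            for lb in labels[i:]:
                key = frozenset({la, lb}) if la != lb else frozenset({la})
                mat.loc[la, lb] = self.mean_distance[key]
        return mat

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for (fixed, randomized), p in sorted(self.p_empirical.items()):
            key = frozenset({fixed, randomized}) if fixed != randomized else frozenset({fixed})
            rows.append(
                {
                    "group_fixed": fixed,
                    "group_randomized": randomized,
                    "mean_distance": self.mean_distance[key],
                    "p_empirical": p,
                    "n_random": self.n_random,
                    "rng_seed": self.rng_seed,
                }
            )
        return pd.DataFrame(rows)


class _DistanceIndex:
    """BFS distance rows from selected sources, as dense integer arrays.

    Rows are cached per source so that thousands of random target sets can be
    scored by indexing rather than by repeated traversal.
    """

    def __init__(self, net: AggregatedNetwork):
        self.graph = net.graph
        self.nodes = sorted(self.graph.nodes)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self._rows: Dict[str, np.ndarray] = {}

    def row(self, source: str) -> np.ndarray:
        cached = self._rows.get(source)
        if cached is None:
            lengths = nx.single_source_shortest_path_length(self.graph, source)
            cached = np.full(len(self.nodes), -1, dtype=np.int64)
            for node, d in lengths.items():
                cached[self.index[node]] = d
            self._rows[source] = cached
        return cached

    def mean_between(self, A: Iterable[str], B: Iterable[str]) -> float:
        A, B = list(A), list(B)
        b_idx = np.array([self.index[b] for b in B], dtype=np.int64)
        total = 0.0
        n_pairs = 0
        for a in A:
            row = self.row(a)[b_idx]
            mask = np.array([b != a for b in B])
            vals = row[mask]
            if np.any(vals < 0):
                raise ValueError(f"node pair disconnected from source {a!r}")
            total += vals.sum()
            n_pairs += int(mask.sum())
        if n_pairs == 0:
            raise ValueError("no valid gene pair between the two sets")
        # A == B as sets: ordered-pair mean equals unordered-pair mean.
        return total / n_pairs


def _check_subset(net: AggregatedNetwork, genes: Iterable[str], what: str) -> set:
    genes = set(genes)
    missing = genes - set(net.graph.nodes)
    if missing:
        raise ValueError(f"{what} gene(s) not in network: {sorted(missing)}")
    return genes


def avg_shortest_distance(net: AggregatedNetwork, A: Iterable[str], B: Iterable[str]) -> float:
    """Mean shortest-path length over all pairs (a, b), a in A, b in B, a != b."""
    A = _check_subset(net, A, "A")
    B = _check_subset(net, B, "B")
    return _DistanceIndex(net).mean_between(A, B)


def _null_means(
    index: _DistanceIndex, A: set, size: int, cfg: NullConfig, rng: np.random.Generator
) -> np.ndarray:
    """Distances from fixed A to ``cfg.n_random`` uniform node sets of ``size``."""
    universe = [n for n in index.nodes if not (cfg.exclude_query and n in A)]
    if size > len(universe):
        raise ValueError(f"random set size {size} exceeds universe of {len(universe)}")
    uni_idx = np.array([index.index[n] for n in universe], dtype=np.int64)
    a_rows = np.vstack([index.row(a) for a in sorted(A)])  # |A| x n_nodes
    a_pos = {index.index[a]: i for i, a in enumerate(sorted(A))}
    means = np.empty(cfg.n_random)
    for t in range(cfg.n_random):
        while True:
            pick = uni_idx[rng.choice(len(uni_idx), size=size, replace=False)]
            sub = a_rows[:, pick]
            if np.any(sub < 0):
                raise ValueError("random set disconnected from a query gene")
            total = float(sub.sum())
            n_pairs = sub.size
            # self-pairs (a random gene coinciding with a query gene) carry no
            # distance and are excluded, as in the statistic itself
            for j, node_idx in enumerate(pick):
                if node_idx in a_pos:
                    total -= float(sub[a_pos[node_idx], j])
                    n_pairs -= 1
            if n_pairs > 0:
                means[t] = total / n_pairs
                break
            # a draw identical to a singleton query has no valid pair: redraw
    return means


def empirical_p(
    net: AggregatedNetwork, A: Iterable[str], B: Iterable[str], cfg: NullConfig
) -> EmpiricalResult:
    """Directional empirical p-value of the A-B distance; B is the randomized side."""
    A = _check_subset(net, A, "A")
    B = _check_subset(net, B, "B")
    index = _DistanceIndex(net)
    real = index.mean_between(A, B)
    rng = np.random.default_rng(cfg.rng_seed)
    nulls = _null_means(index, A, len(B), cfg, rng)
    if cfg.strict_less:
        p = float(np.sum(nulls < real)) / cfg.n_random
    else:
        p = float(np.sum(nulls <= real)) / cfg.n_random
    return EmpiricalResult(p=p, real_distance=real, null_distances=nulls)


def random_baseline(
    net: AggregatedNetwork,
    A: Iterable[str] = None,
    size: int = None,
    cfg: NullConfig = NullConfig(),
    size_a: int = None,
) -> float:
    """Mean distance from A (or from a fresh random set per draw) to random sets.

    With ``A`` given, returns the mean over ``cfg.n_random`` draws of the
    A-to-random-set distance (``size`` defaults to |A|).  With ``A`` omitted,
    both sides are randomized per draw (``size_a`` required), giving the
    random-vs-random baseline.
    """
    index = _DistanceIndex(net)
    rng = np.random.default_rng(cfg.rng_seed)
    if A is not None:
        A = _check_subset(net, A, "A")
        size = size if size is not None else len(A)
        return float(np.mean(_null_means(index, A, size, cfg, rng)))
    if size_a is None or size is None:
        raise ValueError("random-vs-random baseline needs size_a and size")
    nodes = list(index.nodes)
    means = np.empty(cfg.n_random)
    for t in range(cfg.n_random):
        a_set = set(rng.choice(len(nodes), size=size_a, replace=False))
        a_genes = {nodes[i] for i in a_set}
        one = replace(cfg, n_random=1)
        means[t] = _null_means(index, a_genes, size, one, rng)[0]
    return float(np.mean(means))


def distance_table(
    net: AggregatedNetwork, groups: dict, cfg: NullConfig
) -> DistanceTable:
    """Intra/inter-group distances plus random baselines with directional p-values.

    ``groups`` maps label -> gene set, in presentation order.  The returned
    table carries one mean distance per unordered label pair (including each
    group against a size-matched random baseline and random-vs-random) and a
    directional empirical p-value for every ordered pair of real groups.
    """
    labels = tuple(groups)
    for label, genes in groups.items():
        _check_subset(net, genes, label)
    index = _DistanceIndex(net)
    rng = np.random.default_rng(cfg.rng_seed)

    mean_distance = {}
    p_empirical = {}
    for i, la in enumerate(labels):
        for lb in labels[i:]:
            key = frozenset({la, lb}) if la != lb else frozenset({la})
            if la == lb and len(groups[la]) < 2:
                mean_distance[key] = float("nan")  # no distinct pair exists
            else:
                mean_distance[key] = index.mean_between(groups[la], groups[lb])

    for la in labels:  # directional nulls, intra included
        for lb in labels:
            key = frozenset({la, lb}) if la != lb else frozenset({la})
            real = mean_distance[key]
            if real != real:  # undefined singleton intra cell
                continue
            nulls = _null_means(index, set(groups[la]), len(groups[lb]), cfg, rng)
            if cfg.strict_less:
                p_empirical[(la, lb)] = float(np.sum(nulls < real)) / cfg.n_random
            else:
                p_empirical[(la, lb)] = float(np.sum(nulls <= real)) / cfg.n_random

    # random baselines: one per group (size-matched) plus random-vs-random
    for la in labels:
        mean_distance[frozenset({la, "Random"})] = random_baseline(
            net, groups[la], size=len(groups[la]), cfg=cfg
        )
    mean_size = int(round(np.mean([len(g) for g in groups.values()])))
    mean_distance[frozenset({"Random"})] = random_baseline(
        net, size=mean_size, size_a=mean_size, cfg=cfg
    )

    return DistanceTable(
        mean_distance=mean_distance,
        p_empirical=p_empirical,
        n_random=cfg.n_random,
        rng_seed=cfg.rng_seed,
        labels=labels + ("Random",),
    )
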