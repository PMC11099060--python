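"""Neighborhood overlap and its label-randomization significance.

The observed statistic is the raw intersection size of the top-k network
neighborhoods seeded by two gene groups.  Under the null, the group labels of
all labeled genes are permuted jointly (all labels reshuffle, not only the
two groups under test, so group sizes are preserved by construction), both
neighborhoods are recomputed, and the empirical p-value is the fraction of
permutations whose overlap is less than or equal to the observed one — small
values mean the real neighborhoods share fewer genes than label-exchangeable
ones would.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .multiplex import MultiplexNetwork
from .rwr import Neighborhood, RWRConfig, SupraWalker, extract_neighborhood

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapResult:
    real_overlap: int
    p_low: float
    n_randomizations: int
    rng_seed: int
    null_overlaps: tuple

    def to_dict(self) -> dict:
        return {
            "real_overlap": self.real_overlap,
            "p_low": self.p_low,
            "n_randomizations": self.n_randomizations,
            "rng_seed": self.rng_seed,
        }


def neighborhood_overlap(na: Neighborhood, nb: Neighborhood) -> int:
    """Number of genes shared by two neighborhoods."""
    return len(na.gene_set & nb.gene_set)


def label_randomization_test(
    mx: MultiplexNetwork,
    labeled_genes: dict,
    group_a: str,
    group_b: str,
    k: int = 50,
    n_rand: int = 1000,
    cfg: RWRConfig = RWRConfig(),
    rng_seed: int = 42,
    permuter=None,
) -> OverlapResult:
    """Overlap of the group_a/group_b top-k neighborhoods vs permuted labels.

    ``labeled_genes`` maps gene -> group label for every labeled gene; genes
    absent from the network cannot seed a walk and are dropped (with a
    warning) before permuting, so the permutation universe is the
    network-present labeled genes only.  ``permuter`` (rng, labels-array ->
    permuted labels-array) exists for tests; the default is a uniform shuffle.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    present = {g: lab for g, lab in labeled_genes.items() if g in mx.nodes}
    dropped = set(labeled_genes) - set(present)
    if dropped:
        log.warning(
            "%d labeled gene(s) not in network, excluded from permutation: %s",
            len(dropped),
            ", ".join(sorted(dropped)),
        )
    genes = sorted(present)
    labels = np.array([present[g] for g in genes], dtype=object)
    for group in (group_a, group_b):
        if group not in set(labels):
            raise ValueError(f"group {group!r} has no network-present gene")

    walker = SupraWalker(mx, cfg)

    def overlap_for(lab_array: np.ndarray) -> int:
        seeds_a = [g for g, lab in zip(genes, lab_array) if lab == group_a]
        seeds_b = [g for g, lab in zip(genes, lab_array) if lab == group_b]
        na = extract_neighborhood(walker.scores(seeds_a), k, seed_group=group_a)
        nb = extract_neighborhood(walker.scores(seeds_b), k, seed_group=group_b)
        return neighborhood_overlap(na, nb)

    real = overlap_for(labels)
    rng = np.random.default_rng(rng_seed)
    if permuter is None:
        permuter = lambda rng, lab: lab[rng.permutation(len(lab))]
    nulls = []
    for _ in range(n_rand):
        permuted = permuter(rng, labels)
        counts = {lab: int(np.sum(permuted == lab)) for lab in set(labels)}
        expected = {lab: int(np.sum(labels == lab)) for lab in set(labels)}
        if counts != expected:
            raise AssertionError("permutation changed group sizes")
        nulls.append(overlap_for(permuted))
    p_low = float(np.sum(np.asarray(nulls) <= real)) / n_rand
    return OverlapResult(
        real_overlap=real,
        p_low=p_low,
        n_randomizations=n_rand,
        rng_seed=rng_seed,
        null_overlaps=tuple(nulls),
    )
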