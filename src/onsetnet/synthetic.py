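"""Synthetic multiplex benchmark with planted onset-group structure.

The generator emulates the statistical structure the pipeline is designed to
detect, without any external data: each layer is an independent
planted-partition (stochastic block) draw over a shared gene universe, with
two dense functional communities (a "sarcomere-like" and a "sarcolemma-like"
module) embedded in a sparse background.  Three gene groups are planted:

* a distal-like group sampled inside community 1,
* a proximal-like group sampled inside community 2,
* a common-like "bridge" group drawn from the background, internally wired
  at the within-community density and attached into both communities —
  a small multifunctional cluster straddling the two modules, annotated
  with both community terms in the matching GMT.

The bundle is deterministic given its seed: the same configuration and seed
reproduce byte-identical files.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import AnnotationDatabase, Term, write_gmt
from .multiplex import Layer, MultiplexNetwork, build_multiplex

#: Layer names used when exactly three layers are generated.
DEFAULT_LAYER_NAMES = ("ppi", "complexes", "pathways")

GROUP_LABELS = ("distal_like", "proximal_like", "common_like")
COMMUNITY_TERMS = ("sarcomere_like", "sarcolemma_like")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters.

    Group sizes default to 11/22/7 to mirror the real onset-group split;
    ``p_intra`` and ``p_inter`` are per-layer edge probabilities within
    communities and elsewhere; ``bridge_attachment`` is the per-layer,
    per-community probability that a common-like gene wires into that
    community (when it does, it links to members at ``p_intra``).
    """

    n_genes: int = 300
    n_layers: int = 3
    community_sizes: tuple = (60, 60)
    p_intra: float = 0.15
    p_inter: float = 0.01
    group_sizes: tuple = (11, 22, 7)
    bridge_attachment: float = 0.3
    n_terms: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_intra, self.p_inter, self.bridge_attachment):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")
        if len(self.community_sizes) != 2 or len(self.group_sizes) != 3:
            raise ValueError("expected 2 community sizes and 3 group sizes")
        if sum(self.community_sizes) > self.n_genes:
            raise ValueError("communities do not fit in the gene universe")
        if self.group_sizes[0] > self.community_sizes[0]:
            raise ValueError("distal-like group larger than community 1")
        if self.group_sizes[1] > self.community_sizes[1]:
            raise ValueError("proximal-like group larger than community 2")
        n_background = self.n_genes - sum(self.community_sizes)
        if self.group_sizes[2] > n_background:
            raise ValueError("common-like group larger than the background")
        if self.n_terms < 2:
            raise ValueError("need at least the two community terms")


@dataclass(frozen=True)
class SyntheticBundle:
    config: SyntheticConfig
    genes: tuple
    layers: tuple                 # Layer objects
    groups: dict                  # label -> frozenset of genes
    gmt: AnnotationDatabase
    truth: dict                   # gene -> {"community": str, "group": str}

    def multiplex(self) -> MultiplexNetwork:
        mx = build_multiplex(self.layers)
        # keep isolated genes in the universe so downstream missing-gene
        # reporting is exercised on realistic input
        return MultiplexNetwork(nodes=frozenset(self.genes), layers=mx.layers)

    def labels(self) -> dict:
        """gene -> group label, for the planted genes only."""
        return {g: lab for lab, genes in self.groups.items() for g in genes}


def _pairs(members: np.ndarray, p: float, rng: np.random.Generator) -> set:
    """Bernoulli(p) edges over all unordered pairs of ``members`` (index array)."""
    m = len(members)
    if m < 2 or p == 0.0:
        return set()
    iu, ju = np.triu_indices(m, k=1)
    mask = rng.random(len(iu)) < p
    return {(int(members[i]), int(members[j])) for i, j in zip(iu[mask], ju[mask])}


def generate(cfg: SyntheticConfig) -> SyntheticBundle:
    """Draw one synthetic bundle (networks, gene groups, annotations, truth)."""
    rng = np.random.default_rng(cfg.rng_seed)
    width = max(4, len(str(cfg.n_genes)))
    genes = tuple(f"G{i:0{width}d}" for i in range(1, cfg.n_genes + 1))
    c1_n, c2_n = cfg.community_sizes
    comm1 = np.arange(0, c1_n)
    comm2 = np.arange(c1_n, c1_n + c2_n)
    background = np.arange(c1_n + c2_n, cfg.n_genes)

    d_n, p_n, b_n = cfg.group_sizes
    distal = np.sort(rng.choice(comm1, size=d_n, replace=False))
    proximal = np.sort(rng.choice(comm2, size=p_n, replace=False))
    bridge = np.sort(rng.choice(background, size=b_n, replace=False))

    layer_names = (
        DEFAULT_LAYER_NAMES
        if cfg.n_layers == 3
        else tuple(f"layer{i+1:02d}" for i in range(cfg.n_layers))
    )
    layers = []
    all_idx = np.arange(cfg.n_genes)
    for name in layer_names:
        edges = _pairs(all_idx, cfg.p_inter, rng)
        edges |= _pairs(comm1, cfg.p_intra, rng)
        edges |= _pairs(comm2, cfg.p_intra, rng)
        edges |= _pairs(bridge, cfg.p_intra, rng)
        for b in bridge:
            for comm in (comm1, comm2):
                if rng.random() >= cfg.bridge_attachment:
                    continue
                mask = rng.random(len(comm)) < cfg.p_intra
                members = comm[mask]
                if len(members) == 0:
                    members = comm[[rng.integers(len(comm))]]
                for m in members:
                    i, j = (int(b), int(m)) if b < m else (int(m), int(b))
                    edges.add((i, j))
        layer_edges = frozenset(
            (genes[i], genes[j]) for i, j in edges  # i < j, and symbols sort like indices
        )
        layers.append(Layer(name=name, edges=layer_edges))

    groups = {
        "distal_like": frozenset(genes[i] for i in distal),
        "proximal_like": frozenset(genes[i] for i in proximal),
        "common_like": frozenset(genes[i] for i in bridge),
    }

    terms = {
        "sarcomere_like": Term(
            term_id="sarcomere_like",
            name="community 1 localization",
            genes=frozenset(genes[i] for i in comm1) | groups["common_like"],
        ),
        "sarcolemma_like": Term(
            term_id="sarcolemma_like",
            name="community 2 localization",
            genes=frozenset(genes[i] for i in comm2) | groups["common_like"],
        ),
    }
    for t in range(cfg.n_terms - 2):
        size = int(rng.integers(10, 41))
        members = np.sort(rng.choice(all_idx, size=min(size, cfg.n_genes), replace=False))
        tid = f"NOISE_{t+1:02d}"
        terms[tid] = Term(
            term_id=tid,
            name=f"random annotation {t+1}",
            genes=frozenset(genes[i] for i in members),
        )
    background_genes = frozenset().union(*(t.genes for t in terms.values()))
    gmt = AnnotationDatabase(terms=terms, background=background_genes)

    community_of = {}
    for i in comm1:
        community_of[genes[i]] = "community1"
    for i in comm2:
        community_of[genes[i]] = "community2"
    for i in background:
        community_of[genes[i]] = "background"
    group_of = {g: lab for lab, gs in groups.items() for g in gs}
    truth = {
        g: {"community": community_of[g], "group": group_of.get(g, "")} for g in genes
    }
    return SyntheticBundle(
        config=cfg, genes=genes, layers=tuple(layers), groups=groups, gmt=gmt, truth=truth
    )


def truth_report(bundle: SyntheticBundle) -> pd.DataFrame:
    """Planted memberships as a table (gene, community, group)."""
    return pd.DataFrame(
        [
            {"gene": g, "community": v["community"], "group": v["group"]}
            for g, v in bundle.truth.items()
        ]
    )


def write_bundle(bundle: SyntheticBundle, out_dir) -> dict:
    """Write the bundle in the exact formats the pipeline reads; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"layers": {}, "groups": {}}
    for layer in bundle.layers:
        p = out / f"layer_{layer.name}.tsv"
        lines = [f"{a}\t{b}" for a, b in sorted(layer.edges)]
        p.write_text("\n".join(lines) + ("\n" if lines else ""))
        paths["layers"][layer.name] = p
    for label, genes in bundle.groups.items():
        p = out / f"genes_{label}.txt"
        p.write_text("\n".join(sorted(genes)) + "\n")
        paths["groups"][label] = p
    gmt_path = out / "annotations.gmt"
    write_gmt(bundle.gmt, gmt_path)
    paths["gmt"] = gmt_path
    truth_path = out / "truth.tsv"
    truth_report(bundle).to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths


def bundle_digest(out_dir) -> str:
    """SHA-256 over all files of a written bundle (determinism checks)."""
    h = hashlib.sha256()
    for p in sorted(Path(out_dir).rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()
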