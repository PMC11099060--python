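"""End-to-end pipeline: curation -> network -> distances -> RWR -> overlap -> enrichment.

One global seed deterministically derives per-stage seeds (by hashing the
stage name), so a full run is reproducible and each stage can be re-run
standalone with the same randomness.  All stage outputs land in a run
directory together with a manifest recording every parameter.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import multiplex as mxmod
from .distances import NullConfig, distance_table
from .enrichment import enrich, read_gmt, rows_to_frame
from .gene_sets import read_gene_list
from .overlap import label_randomization_test
from .rwr import RWRConfig, SupraWalker, extract_neighborhood, score_table

log = logging.getLogger(__name__)


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    layer_paths: dict                  # layer name -> edge-list TSV
    group_paths: dict                  # group label -> gene-list file
    gmt_path: str
    out_dir: str
    k_values: tuple = (50, 100)
    n_rand_overlap: int = 1000
    null: NullConfig = field(default_factory=NullConfig)
    rwr: RWRConfig = field(default_factory=RWRConfig)
    seed: int = 42

    def validate(self) -> None:
        for k in self.k_values:
            if k < 1:
                raise ValueError("k must be >= 1")
        missing = [
            str(p)
            for p in [*self.layer_paths.values(), *self.group_paths.values(), self.gmt_path]
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


def load_config(path) -> PipelineConfig:
    """Pipeline configuration from a YAML mapping."""
    raw = yaml.safe_load(Path(path).read_text())
    null = NullConfig(**raw.get("null", {}))
    rwr = RWRConfig(**raw.get("rwr", {}))
    return PipelineConfig(
        layer_paths=dict(raw["layer_paths"]),
        group_paths=dict(raw["group_paths"]),
        gmt_path=raw["gmt_path"],
        out_dir=raw["out_dir"],
        k_values=tuple(raw.get("k_values", (50, 100))),
        n_rand_overlap=int(raw.get("n_rand_overlap", 1000)),
        null=null,
        rwr=rwr,
        seed=int(raw.get("seed", 42)),
    )


def _stage(name: str):
    log.info("stage: %s", name)
    return name


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage; returns the run directory.

    Stage order: read groups -> build multiplex -> largest connected
    component -> induced subnetwork + centrality -> distance table -> RWR
    neighborhoods per group and k -> pairwise overlap randomization tests
    (smallest k) -> enrichment of groups and neighborhoods.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    _stage("curate")
    groups = {
        label: frozenset(read_gene_list(path)) for label, path in cfg.group_paths.items()
    }
    pd.DataFrame(
        [(g, label) for label, genes in groups.items() for g in sorted(genes)],
        columns=["gene", "group"],
    ).to_csv(out / "groups.tsv", sep="\t", index=False)

    _stage("build-net")
    layers = [mxmod.read_layer(path, name) for name, path in cfg.layer_paths.items()]
    mx_full = mxmod.build_multiplex(layers)
    mx = mxmod.largest_connected_component(mx_full)
    net = mxmod.aggregate(mx)
    summary = mxmod.summarize_network(net)

    all_group_genes = frozenset().union(*groups.values())
    missing = sorted(all_group_genes - mx.nodes)
    (out / "genes_not_in_network.txt").write_text("\n".join(missing) + ("\n" if missing else ""))
    net_groups = {label: genes & mx.nodes for label, genes in groups.items()}
    for label, genes in net_groups.items():
        if not genes:
            raise ValueError(f"group {label!r} has no gene in the network")

    _stage("subnet")
    labels_by_gene = {g: label for label, genes in groups.items() for g in genes}
    sub = mxmod.induced_subnetwork(mxmod.aggregate(mx_full), all_group_genes & frozenset().union(mx_full.nodes))
    mxmod.write_graphml(sub.network, out / "subnetwork.graphml", node_groups=labels_by_gene)
    mxmod.write_sif(sub.network, out / "subnetwork.sif")
    mxmod.write_graphml(net, out / "aggregated.graphml", node_groups=labels_by_gene)
    closeness = mxmod.closeness_centrality(sub.network)
    pd.DataFrame(
        sorted(closeness.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene", "closeness"],
    ).to_csv(out / "subnetwork_closeness.tsv", sep="\t", index=False)

    _stage("distances")
    null_cfg = replace(cfg.null, rng_seed=derive_seed(cfg.seed, "distances"))
    table = distance_table(net, net_groups, null_cfg)
    table.to_matrix().to_csv(out / "distance_matrix.tsv", sep="\t")
    table.to_long_frame().to_csv(out / "distance_pvalues.tsv", sep="\t", index=False)

    _stage("rwr")
    walker = SupraWalker(mx, cfg.rwr)
    neighborhoods = {}
    for label, genes in net_groups.items():
        sv = walker.scores(genes)
        score_table(sv).to_csv(out / f"rwr_scores_{label}.tsv", sep="\t", index=False)
        for k in cfg.k_values:
            nb = extract_neighborhood(sv, k, seed_group=label)
            neighborhoods[(label, k)] = nb
            pd.DataFrame({"gene": nb.genes, "rank": range(1, len(nb.genes) + 1)}).to_csv(
                out / f"neighborhood_{label}_top{k}.tsv", sep="\t", index=False
            )

    _stage("overlap")
    k_main = min(cfg.k_values)
    labeled = {g: label for label, genes in net_groups.items() for g in genes}
    overlap_results = {}
    labels = sorted(net_groups)
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            res = label_randomization_test(
                mx,
                labeled,
                la,
                lb,
                k=k_main,
                n_rand=cfg.n_rand_overlap,
                cfg=cfg.rwr,
                rng_seed=derive_seed(cfg.seed, f"overlap:{la}:{lb}"),
            )
            overlap_results[f"{la}__{lb}"] = res.to_dict()
            pd.DataFrame({"null_overlap": res.null_overlaps}).to_csv(
                out / f"overlap_null_{la}__{lb}.tsv", sep="\t", index=False
            )
    (out / "overlap_results.json").write_text(json.dumps(overlap_results, indent=2) + "\n")

    _stage("enrich")
    db = read_gmt(cfg.gmt_path)
    for label, genes in groups.items():
        rows_to_frame(enrich(genes, db)).to_csv(
            out / f"enrichment_{label}.tsv", sep="\t", index=False
        )
    for (label, k), nb in neighborhoods.items():
        rows_to_frame(enrich(nb.gene_set, db)).to_csv(
            out / f"enrichment_neighborhood_{label}_top{k}.tsv", sep="\t", index=False
        )

    manifest = {
        "seed": cfg.seed,
        "stage_seeds": {
            "distances": derive_seed(cfg.seed, "distances"),
            **{
                f"overlap:{la}:{lb}": derive_seed(cfg.seed, f"overlap:{la}:{lb}")
                for i, la in enumerate(labels)
                for lb in labels[i + 1 :]
            },
        },
        "k_values": list(cfg.k_values),
        "n_rand_overlap": cfg.n_rand_overlap,
        "null": asdict(cfg.null),
        "rwr": asdict(cfg.rwr),
        "layer_paths": {k: str(v) for k, v in cfg.layer_paths.items()},
        "group_paths": {k: str(v) for k, v in cfg.group_paths.items()},
        "gmt_path": str(cfg.gmt_path),
        "network_summary": {
            "n_nodes": summary.n_nodes,
            "n_edges": summary.n_edges,
            "n_components": summary.n_components,
            "density": summary.density,
        },
        "genes_not_in_network": missing,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
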