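#!/usr/bin/env python
"""Assign the curated muscular-dystrophy genes to onset groups.

Reads the packaged distal and proximal gene lists (already filtered for
Moderate/Strong/Definitive evidence plus the literature whitelist), splits
them into distal-only (DoGs), proximal-only (PoGs) and common (CoGs) groups,
and writes the assignment under results/.
"""

from pathlib import Path

from onsetnet.gene_sets import load_md_onset_groups, write_groups_json, write_groups_tsv

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    groups = load_md_onset_groups()
    write_groups_tsv(groups, OUT / "onset_groups.tsv")
    write_groups_json(groups, OUT / "onset_groups.json")
    print(
        f"{len(groups.all_genes)} muscular-dystrophy genes assigned: "
        f"{len(groups.dogs)} distal-only, {len(groups.pogs)} proximal-only, "
        f"{len(groups.cogs)} common"
    )
    print(f"common genes: {', '.join(sorted(groups.cogs))}")
    print(f"wrote {OUT / 'onset_groups.tsv'}")


if __name__ == "__main__":
    main()
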