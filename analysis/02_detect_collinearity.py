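"""Detect collinear blocks on the simulated genome and score significance.

Reads results/study/, writes the block report and a dot-plot export
(rank_a, rank_b, best/second/other label) for plotting.
"""

from __future__ import annotations

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import STUDY, study_config

from polyretain.collinearity import colinear_gene_set, find_blocks, rank_hit_classes
from polyretain.homology import filter_anchors
from polyretain.io import read_gene_positions, read_similarity_table, write_block_report
from polyretain.util import child_seed


def main() -> None:
    cfg = study_config()
    genes = read_gene_positions(STUDY / "gene_positions.tsv")
    similarity = read_similarity_table(STUDY / "similarity.tsv")
    anchors = filter_anchors(similarity)
    params = cfg.collinearity.__class__(
        max_gap=cfg.collinearity.max_gap,
        min_anchors=cfg.collinearity.min_anchors,
        n_permutations=cfg.collinearity.n_permutations,
        seed=child_seed(cfg.sim.seed, "permutation"),
    )
    blocks = find_blocks(genes, anchors, params)
    write_block_report(blocks, STUDY / "blocks.tsv")
    labels = rank_hit_classes(similarity)
    idx = {g.gene_id: g for g in genes}
    with open(STUDY / "dotplot.tsv", "w") as fh:
        fh.write("rank_a\trank_b\tlabel\n")
        for (q, s), lab in sorted(labels.items()):
            fh.write(f"{idx[q].rank}\t{idx[s].rank}\t{lab}\n")
    sig = [b for b in blocks if b.p_value is not None and b.p_value < params.p_max]
    colinear = colinear_gene_set(blocks, params.p_max)
    print(
        f"{len(anchors)} filtered anchors chained into {len(blocks)} blocks, "
        f"{len(sig)} significant (p < {params.p_max}); {len(colinear)} of "
        f"{len(genes)} genes are collinear"
    )


if __name__ == "__main__":
    main()
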