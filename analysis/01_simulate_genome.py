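"""Simulate the canonical polyploid genome and emit its raw study inputs.

Writes gene positions, the all-vs-all similarity table, the ground-truth
table, and the reference interaction network under results/study/.
"""

from __future__ import annotations

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import STUDY, study_config

from polyretain.io import write_edge_list, write_gene_positions, write_similarity_table
from polyretain.simulate import emit_reference_network, emit_similarity_table, simulate_genome
from polyretain.util import child_seed


def main() -> None:
    cfg = study_config()
    STUDY.mkdir(parents=True, exist_ok=True)
    genes, truth = simulate_genome(cfg.sim, cfg.events)
    similarity = emit_similarity_table(
        genes, truth, identity_decay=cfg.sim.identity_decay,
        seed=child_seed(cfg.sim.seed, "similarity"),
    )
    ref_edges = emit_reference_network(
        truth, cfg.network_mean_degree, seed=child_seed(cfg.sim.seed, "network")
    )
    write_gene_positions(genes, STUDY / "gene_positions.tsv")
    write_similarity_table(similarity, STUDY / "similarity.tsv")
    truth.to_tsv(STUDY / "truth.tsv")
    write_edge_list(ref_edges, STUDY / "reference_network.tsv")
    with open(STUDY / "focal_seeds.txt", "w") as fh:
        for g in sorted(truth.ancestral_focal):
            fh.write(g + "\n")
    n_wgd = (truth.genes.dup_type_truth == "wgd").sum()
    print(
        f"simulated {len(genes)} genes from {cfg.sim.n_genes} ancestral loci "
        f"({n_wgd} polyploidy-derived by truth), {len(similarity)} similarity "
        f"rows, {len(ref_edges)} reference interactions -> {STUDY}"
    )


if __name__ == "__main__":
    main()
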