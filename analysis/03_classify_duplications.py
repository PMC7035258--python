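"""Assign the five duplication types and compare against simulated truth.

Writes the per-gene type map and the five-way summary table.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import STUDY, study_config

from polyretain.classify import classify_duplicates, summarize_types
from polyretain.homology import filter_anchors
from polyretain.io import read_block_report, read_gene_positions, read_similarity_table


def main() -> None:
    cfg = study_config()
    genes = read_gene_positions(STUDY / "gene_positions.tsv")
    anchors = filter_anchors(read_similarity_table(STUDY / "similarity.tsv"))
    blocks = [
        b
        for b in read_block_report(STUDY / "blocks.tsv")
        if b.p_value is not None and b.p_value < cfg.collinearity.p_max
    ]
    dup_map = classify_duplicates(genes, anchors, blocks, cfg.classifier)
    pd.DataFrame(sorted(dup_map.items()), columns=["gene_id", "dup_type"]).to_csv(
        STUDY / "dup_types.tsv", sep="\t", index=False
    )
    summary = summarize_types(dup_map, [g.gene_id for g in genes])
    rows = [
        {"type": t, "count": summary.counts[t], "percent": summary.percents[t]}
        for t in summary.counts
    ]
    pd.DataFrame(rows).to_csv(STUDY / "type_summary.tsv", sep="\t", index=False)

    truth = pd.read_csv(STUDY / "truth.tsv", sep="\t")
    truth_types = dict(zip(truth.gene_id, truth.dup_type_truth))
    agree = sum(dup_map[g] == truth_types[g] for g in dup_map) / len(dup_map)
    print("five-way duplication summary:")
    for r in rows:
        print(f"  {r['type']:<10} {r['count']:>6}  {r['percent']:>7}%")
    print(f"agreement with simulated truth: {agree:.3f}")


if __name__ == "__main__":
    main()
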