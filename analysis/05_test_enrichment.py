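"""Chi-squared enrichment of the focal class in collinear regions and per
duplication type, with I/U/D status calls.

Writes the collinearity-enrichment row and the per-type enrichment table.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import STUDY, study_config

from polyretain.collinearity import colinear_gene_set
from polyretain.enrichment import enrichment_row, type_enrichment_table
from polyretain.homology import FamilyLibrary, identify_family_members
from polyretain.io import read_block_report, read_gene_positions, read_id_list, read_similarity_table
from polyretain.util import format_percent


def main() -> None:
    cfg = study_config()
    genes = read_gene_positions(STUDY / "gene_positions.tsv")
    similarity = read_similarity_table(STUDY / "similarity.tsv")
    blocks = read_block_report(STUDY / "blocks.tsv")
    colinear = colinear_gene_set(blocks, cfg.collinearity.p_max)
    seeds = set(read_id_list(STUDY / "focal_seeds.txt"))
    lib = FamilyLibrary(frozenset(seeds), frozenset(seeds))
    focal = seeds | identify_family_members(lib, similarity, cfg.family)
    universe = [g.gene_id for g in genes]

    res = enrichment_row(focal, colinear, universe, cfg.enrichment)
    row = {
        "dataset": "simulated",
        "all_colinear": len(colinear),
        "all_total": len(universe),
        "all_percent": format_percent(len(colinear), len(universe)),
        "focal_colinear": res.a,
        "focal_total": res.a + res.b,
        "focal_percent": format_percent(res.a, res.a + res.b),
        "chi2": round(res.chi2, 4),
        "p_value": res.p,
        "status": res.status,
    }
    pd.DataFrame([row]).to_csv(STUDY / "enrichment.tsv", sep="\t", index=False)

    dup_map = dict(
        pd.read_csv(STUDY / "dup_types.tsv", sep="\t").itertuples(index=False)
    )
    per_type = type_enrichment_table(dup_map, focal, universe, cfg.enrichment)
    pd.DataFrame(
        [
            {"type": t, "focal_in": r.a, "background_in": r.c, "p_value": r.p, "status": r.status}
            for t, r in per_type.items()
        ]
    ).to_csv(STUDY / "type_enrichment.tsv", sep="\t", index=False)

    print(
        f"focal class: {row['focal_colinear']}/{row['focal_total']} collinear "
        f"({row['focal_percent']}%) vs genome {row['all_percent']}%: "
        f"chi2={row['chi2']}, p={row['p_value']:.3g}, status {row['status']}"
    )
    for t, r in per_type.items():
        print(f"  {t:<10} status {r.status} (p={r.p:.3g})")


if __name__ == "__main__":
    main()
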