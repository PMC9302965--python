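"""Motif-enrichment x expression integration: nominate master TFs of the
target cell state from the synthetic motif and expression tables.
"""

from pathlib import Path

import pandas as pd

from atacpeaks.io_formats import read_tables
from atacpeaks.tf_integration import (
    condition_means,
    deduplicate_motifs,
    log2cpm,
    rank_tfs_by_expression,
    top_candidates,
)

SIM = Path("results/sim")
OUT = Path("results")


def main() -> None:
    motifs = read_tables(SIM / "motifs.tsv", "motifs")
    counts = read_tables(SIM / "expression_counts.tsv", "expression")
    cond_map = (
        pd.read_csv(SIM / "rna_samples.tsv", sep="\t")
        .set_index("sample")["condition"].to_dict()
    )
    expr = condition_means(log2cpm(counts), cond_map)
    ranked = rank_tfs_by_expression(deduplicate_motifs(motifs), expr, "mesc", "mef")

    table = pd.DataFrame(
        [(r.final_rank, r.tf_gene, r.motif_id, r.fdr,
          r.expr_target, r.expr_background, r.expr_diff) for r in ranked],
        columns=["final_rank", "tf_gene", "motif_id", "fdr",
                 "expr_mesc", "expr_mef", "expr_diff"],
    )
    table.to_csv(OUT / "ranked_tfs.tsv", sep="\t", index=False)
    expr.rename_axis("gene_id").to_csv(OUT / "expression_scatter.tsv", sep="\t")

    print(table.head(10).to_string(index=False))
    print(f"\ntop 5 nominated master TFs: {', '.join(top_candidates(ranked))}")
    print("(the generator plants Pou5f1, Sox2, Klf4, Esrrb, Nr5a2 as drivers "
          "of the mESC state)")


if __name__ == "__main__":
    main()
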