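"""Motif-enrichment x expression integration for master-TF nomination.

Candidate drivers of a cell identity should both carry an enriched motif in
that cell type's accessible regions and be robustly expressed there, above
the level in the contrasting cell type.  The procedure: collapse enriched
motifs to one (best-FDR) record per TF, take the top-K by enrichment, keep
TFs expressed above ``expr_min`` log2CPM in the target condition, and
re-rank the survivors by the target-minus-background log2CPM difference.
The top few re-ranked TFs are the nominated master regulators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntegrationParams:
    top_k: int = 25          # 40 is conventional for footprinting-tool outputs
    expr_min: float = 2.0    # log2CPM floor for "robustly expressed"
    n_top_report: int = 5

    def __post_init__(self) -> None:
        if not (self.top_k >= self.n_top_report >= 1):
            raise ValidationError("need top_k >= n_top_report >= 1")


@dataclass(frozen=True)
class RankedTf:
    tf_gene: str
    expr_target: float
    expr_background: float
    final_rank: int
    motif_id: str = ""
    fdr: float = float("nan")

    @property
    def expr_diff(self) -> float:
        return self.expr_target - self.expr_background


def log2cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(CPM + 1) per gene and sample; zero counts map to exactly 0."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValidationError(f"zero library size for sample(s) {bad}")
    cpm = counts / totals * 1e6
    return np.log2(cpm + 1.0)


def condition_means(
    l2cpm: pd.DataFrame, sample_conditions: dict[str, str]
) -> pd.DataFrame:
    """Mean log2CPM per condition (arithmetic mean of replicate values)."""
    groups: dict[str, list[str]] = {}
    for sample, cond in sample_conditions.items():
        groups.setdefault(cond, []).append(sample)
    return pd.DataFrame(
        {cond: l2cpm[cols].mean(axis=1) for cond, cols in groups.items()}
    )


def deduplicate_motifs(motifs: pd.DataFrame) -> pd.DataFrame:
    """One record per tf_gene, keeping its lowest-FDR motif.

    Input is sorted by (fdr, motif_id); survivors keep that enrichment
    order.  Records without a TF gene mapping are skipped with a warning.
    """
    df = motifs.copy()
    missing = df["tf_gene"].isna() | (df["tf_gene"].astype(str).str.strip() == "")
    if missing.any():
        log.warning("deduplicate_motifs: skipping %d motifs without a TF gene", missing.sum())
        df = df[~missing]
    df = df.sort_values(["fdr", "motif_id"], kind="mergesort")
    return df.drop_duplicates(subset="tf_gene", keep="first").reset_index(drop=True)


def rank_tfs_by_expression(
    motifs: pd.DataFrame,
    expr: pd.DataFrame,
    target: str,
    background: str,
    params: IntegrationParams = IntegrationParams(),
) -> list[RankedTf]:
    """Re-rank the top-K enriched (deduplicated) motifs by expression difference.

    ``expr`` holds per-condition mean log2CPM indexed by gene.  TFs with
    target expression <= ``expr_min`` are dropped; TFs absent from the
    expression table are excluded with a warning.  Survivors sort by
    descending expr_diff (ties: lower fdr, then gene symbol).
    """
    for cond in (target, background):
        if cond not in expr.columns:
            raise ValidationError(f"condition {cond!r} missing from expression table")
    top = motifs.sort_values(["fdr", "motif_id"], kind="mergesort").head(params.top_k)

    rows = []
    for r in top.itertuples():
        gene = str(r.tf_gene)
        if gene not in expr.index:
            log.warning("rank_tfs_by_expression: %s absent from expression table", gene)
            continue
        et = float(expr.at[gene, target])
        eb = float(expr.at[gene, background])
        if et <= params.expr_min:
            continue
        rows.append((et - eb, float(r.fdr), gene, et, eb, str(r.motif_id)))
    if not rows:
        log.warning("rank_tfs_by_expression: no TF passed the expression filter")
    rows.sort(key=lambda t: (-t[0], t[1], t[2]))
    return [
        RankedTf(
            tf_gene=gene,
            expr_target=et,
            expr_background=eb,
            final_rank=i + 1,
            motif_id=motif_id,
            fdr=fdr,
        )
        for i, (diff, fdr, gene, et, eb, motif_id) in enumerate(rows)
    ]


def top_candidates(ranked: list[RankedTf], params: IntegrationParams = IntegrationParams()) -> list[str]:
    return [r.tf_gene for r in ranked[: params.n_top_report]]
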