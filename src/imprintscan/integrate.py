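"""Candidate integration: stringent (tier-1) genes and relaxed cluster search.

Tier 1 requires a promoter DMR, imprinted-like expression in at least one
stage, and concordance between the two (a paternal, AG-hypermethylated
promoter DMR silences the paternal allele, so the gene should be
MEG-like; a maternal DMR pairs with PEG-like).  Imprinted genes cluster,
so tier 2 searches a window around each tier-1 TSS (1 Mb wide by
default) under relaxed criteria: a promoter DMR OR imprinted-like
expression suffices.  ASE support, isoform-specificity and proximity to
a germline DMR are annotated but never gate membership.  Genes with a
DMR but flat expression are reported separately as DMR-only genes, the
pattern expected of isoform- or tissue-specific imprinting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .gdmr import GdmrCall
from .model import DMRCall, GeneAnnotation


def concordance(dmr_direction: str, expression_class: str) -> bool:
    """Paternal (AG-hyper) DMR pairs with MEG_like; maternal with PEG_like."""
    return (dmr_direction == "paternal" and expression_class == "MEG_like") or (
        dmr_direction == "maternal" and expression_class == "PEG_like"
    )


def neighborhood_genes(
    anchor_gene: str,
    annotation: dict[str, GeneAnnotation],
    radius_bp: int,
) -> set[str]:
    """Genes whose TSS lies within radius of the anchor TSS, same chromosome."""
    anchor = annotation[anchor_gene]
    lo, hi = anchor.tss - radius_bp, anchor.tss + radius_bp
    return {
        g.gene_id
        for g in annotation.values()
        if g.gene_id != anchor_gene and g.chrom == anchor.chrom and lo <= g.tss <= hi
    }


def assemble_candidates(
    dmr_calls: list[DMRCall],
    expression_calls: dict[str, pd.DataFrame],
    ase_summaries: pd.DataFrame | None,
    gdmr_calls: list[GdmrCall],
    annotation: dict[str, GeneAnnotation],
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the evidence-tiered candidate table.

    ``expression_calls`` maps stage -> classification table indexed by
    gene.  Returns (candidates, dmr_only) DataFrames; candidates are
    ordered by (chrom, TSS) for determinism.
    """
    dmr_by_gene = {c.gene_id: c for c in dmr_calls}
    stages = sorted(expression_calls)

    unknown = [g for g in dmr_by_gene if g not in annotation]
    for stage in stages:
        unknown += [g for g in expression_calls[stage].index if g not in annotation]
    if unknown:
        raise ValueError(f"genes missing from annotation: {sorted(set(unknown))}")

    def expr_class(gene_id: str, stage: str) -> str:
        table = expression_calls.get(stage)
        if table is None or gene_id not in table.index:
            return "not_expressed"
        return str(table.loc[gene_id, "class"])

    def imprinted_in_any_stage(gene_id: str) -> bool:
        return any(expr_class(gene_id, s) in ("MEG_like", "PEG_like") for s in stages)

    def concordant_any_stage(gene_id: str, direction: str) -> bool:
        return any(concordance(direction, expr_class(gene_id, s)) for s in stages)

    ase_by_gene: dict[str, pd.Series] = {}
    if ase_summaries is not None and len(ase_summaries):
        ase_by_gene = {row["gene_id"]: row for _, row in ase_summaries.iterrows()}

    def near_gdmr(gene_id: str) -> bool:
        gene = annotation[gene_id]
        return any(
            g.window.chrom == gene.chrom
            and min(abs(g.window.start - gene.tss), abs(g.window.end - gene.tss)) <= config.cluster_radius_bp
            for g in gdmr_calls
        )

    # tier 1: DMR + imprinted-like expression + concordance
    tier1 = [
        g for g in sorted(dmr_by_gene) if concordant_any_stage(g, dmr_by_gene[g].direction)
    ]

    # tier 2: relaxed criteria in the neighborhood of tier-1 anchors;
    # each member records its nearest anchor
    tier2: dict[str, tuple[str, int]] = {}
    for anchor in tier1:
        a_tss = annotation[anchor].tss
        for g in sorted(neighborhood_genes(anchor, annotation, config.cluster_radius_bp)):
            if g in tier1:
                continue
            if g in dmr_by_gene or imprinted_in_any_stage(g):
                dist = abs(annotation[g].tss - a_tss)
                if g not in tier2 or dist < tier2[g][1]:
                    tier2[g] = (anchor, dist)

    # side list: genes with a DMR but no imprinted-like expression that made
    # neither tier (the pattern of isoform- or tissue-specific imprinting)
    dmr_only = [
        g for g in sorted(dmr_by_gene)
        if g not in tier1 and g not in tier2 and not imprinted_in_any_stage(g)
    ]

    def row_for(gene_id: str, tier: str, anchor: str = "", dist: int | None = None) -> dict:
        gene = annotation[gene_id]
        call = dmr_by_gene.get(gene_id)
        ase = ase_by_gene.get(gene_id)
        classes = {s: expr_class(gene_id, s) for s in stages}
        return {
            "gene_id": gene_id,
            "chrom": gene.chrom,
            "tss": gene.tss,
            "tier": tier,
            "anchor_gene": anchor,
            "distance_bp": dist if dist is not None else "",
            "has_promoter_dmr": call is not None,
            "dmr_direction": call.direction if call else "",
            "dmr_delta_pp": round(call.delta_pp, 4) if call else "",
            "dmr_q": call.q_value if call else "",
            "has_imprinted_expression_ESC": classes.get("ESC") in ("MEG_like", "PEG_like"),
            "has_imprinted_expression_NPC": classes.get("NPC") in ("MEG_like", "PEG_like"),
            "expression_class_ESC": classes.get("ESC", "not_expressed"),
            "expression_class_NPC": classes.get("NPC", "not_expressed"),
            "concordant": call is not None and concordant_any_stage(gene_id, call.direction),
            "ase_support": ase["support"] if ase is not None else "none",
            "isoform_specific": bool(ase["isoform_specific"]) if ase is not None else False,
            "near_gdmr": near_gdmr(gene_id),
        }

    rows = [row_for(g, "1_stringent") for g in tier1]
    rows += [row_for(g, "2_cluster", anchor, dist) for g, (anchor, dist) in tier2.items()]
    candidates = pd.DataFrame(rows)
    if len(candidates):
        candidates = candidates.sort_values(["chrom", "tss", "gene_id"]).reset_index(drop=True)

    dmr_only_rows = [row_for(g, "dmr_only") for g in dmr_only]
    dmr_only_df = pd.DataFrame(dmr_only_rows)
    if len(dmr_only_df):
        dmr_only_df = dmr_only_df.sort_values(["chrom", "tss", "gene_id"]).reset_index(drop=True)
    return candidates, dmr_only_df
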