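"""Allele-specific expression classification.

The allelic ratio at a heterozygous SNP is the minor-allele read fraction,
min(ref, alt) / (ref + alt), in [0, 0.5].  Following the International
Stem Cell Initiative convention, a ratio below 0.15 is monoallelic
expression and a ratio between 0.15 and 0.3 (inclusive) is partially
monoallelic — the pattern imprinted genes display.  Records need more
than 5 reads (>= 20 in stringent mode) to be classified at all.

A gene's support level is the strongest class among its qualifying
records (monoallelic > partially monoallelic > biallelic), with a
discordance flag when records disagree.  Isoform-specific imprinting is
flagged when, within one cell type, one transcript is (partially)
monoallelic while another is biallelic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig

CLASS_ORDER = ["monoallelic", "partially_monoallelic", "biallelic"]


def allelic_ratio(ref_count: int, alt_count: int) -> float:
    """Minor-allele fraction; symmetric in its arguments."""
    total = ref_count + alt_count
    if total <= 0:
        raise ValueError("allelic ratio undefined for zero total reads")
    return min(ref_count, alt_count) / total


def classify_ase(
    ref_count: int,
    alt_count: int,
    config: PipelineConfig,
    stringent: bool = False,
) -> str:
    """Classify one SNP record; returns a class name or ``insufficient_reads``."""
    total = ref_count + alt_count
    threshold = config.ase_stringent_reads if stringent else config.ase_min_reads
    if total < threshold:
        return "insufficient_reads"
    ratio = allelic_ratio(ref_count, alt_count)
    if ratio < config.ase_mono:
        return "monoallelic"
    if ratio <= config.ase_partial:
        return "partially_monoallelic"
    return "biallelic"


def classify_records(
    records: pd.DataFrame,
    config: PipelineConfig,
    stringent: bool = False,
) -> pd.DataFrame:
    """Vectorised per-record classification; adds an ``ase_class`` column."""
    out = records.copy()
    total = out["ref_count"] + out["alt_count"]
    threshold = config.ase_stringent_reads if stringent else config.ase_min_reads
    ratio = np.minimum(out["ref_count"], out["alt_count"]) / total.replace(0, 1)
    cls = np.full(len(out), "biallelic", dtype=object)
    cls[ratio <= config.ase_partial] = "partially_monoallelic"
    cls[ratio < config.ase_mono] = "monoallelic"
    cls[(total < threshold).to_numpy()] = "insufficient_reads"
    out["ase_class"] = cls
    return out


@dataclass
class GeneAseSummary:
    gene_id: str
    support: str  # monoallelic | partially_monoallelic | biallelic | none
    n_records: int
    n_classified: int
    class_counts: dict[str, int]
    mixed: bool
    per_cell_type: dict[str, str]


def gene_ase_summary(
    gene_records: pd.DataFrame,
    config: PipelineConfig,
    stringent: bool = False,
) -> GeneAseSummary:
    """Strongest-class support for one gene, with a discordance (mixed) flag."""
    gene_id = gene_records["gene_id"].iloc[0] if len(gene_records) else ""
    classified = classify_records(gene_records, config, stringent)
    qual = classified[classified["ase_class"] != "insufficient_reads"]
    counts = {c: int((qual["ase_class"] == c).sum()) for c in CLASS_ORDER}
    support = "none"
    for c in CLASS_ORDER:
        if counts[c] > 0:
            support = c
            break
    mixed = sum(v > 0 for v in counts.values()) > 1
    per_ct: dict[str, str] = {}
    if "cell_type" in qual.columns:
        for ct, sub in qual.groupby("cell_type"):
            for c in CLASS_ORDER:
                if (sub["ase_class"] == c).any():
                    per_ct[str(ct)] = c
                    break
    return GeneAseSummary(
        gene_id=str(gene_id),
        support=support,
        n_records=len(gene_records),
        n_classified=len(qual),
        class_counts=counts,
        mixed=mixed,
        per_cell_type=per_ct,
    )


def isoform_specific_flag(
    gene_records: pd.DataFrame,
    config: PipelineConfig,
    stringent: bool = False,
) -> bool:
    """True when one isoform is (partially) monoallelic and another biallelic.

    The contrast must occur within a single cell type: tissue-specific
    imprinting across cell types would otherwise masquerade as
    isoform-specific.  Records without a transcript_id are ignored.
    """
    recs = gene_records[gene_records["transcript_id"].notna()]
    if recs.empty:
        return False
    classified = classify_records(recs, config, stringent)
    qual = classified[classified["ase_class"] != "insufficient_reads"]
    if qual["transcript_id"].nunique() < 2:
        return False
    groups = qual.groupby("cell_type") if "cell_type" in qual.columns else [(None, qual)]
    for _ct, sub in groups:
        mono_t = set(
            sub.loc[sub["ase_class"].isin(["monoallelic", "partially_monoallelic"]), "transcript_id"]
        )
        bi_t = set(sub.loc[sub["ase_class"] == "biallelic", "transcript_id"])
        if mono_t and (bi_t - mono_t):
            return True
    return False


def ase_summary_table(
    records: pd.DataFrame,
    config: PipelineConfig,
    stringent: bool = False,
) -> pd.DataFrame:
    """Per-gene ASE support table over a full record set."""
    rows = []
    for gene_id, sub in records.groupby("gene_id", sort=True):
        s = gene_ase_summary(sub, config, stringent)
        rows.append(
            {
                "gene_id": gene_id,
                "support": s.support,
                "n_records": s.n_records,
                "n_classified": s.n_classified,
                "n_monoallelic": s.class_counts["monoallelic"],
                "n_partially_monoallelic": s.class_counts["partially_monoallelic"],
                "n_biallelic": s.class_counts["biallelic"],
                "mixed": s.mixed,
                "isoform_specific": isoform_specific_flag(sub, config, stringent),
            }
        )
    cols = [
        "gene_id", "support", "n_records", "n_classified", "n_monoallelic",
        "n_partially_monoallelic", "n_biallelic", "mixed", "isoform_specific",
    ]
    return pd.DataFrame(rows, columns=cols)
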