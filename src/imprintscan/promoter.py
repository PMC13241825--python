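"""Parent-of-origin differentially methylated promoter calling.

The promoter of each expressed gene (TSS +/- 500 bp by default) is
summarised per sample as a pooled-count methylation mean, then tested
between androgenetic (AG) and parthenogenetic (PG) samples.  Two test
units are supported:

* ``cpg_level`` (default) — two-sided Mann-Whitney on all per-sample
  per-CpG methylation levels in the window, AG pool vs PG pool.  With
  small sample groups this is the only unit with enough resolution to
  survive genome-wide FDR control.
* ``sample_mean`` — exact two-sided Wilcoxon rank-sum on per-sample
  promoter means.  With 4v4 groups its minimum two-sided p is 2/70.

Calls require both BH q <= alpha and |AG - PG| >= a minimum delta in
percentage points; direction is ``paternal`` (AG-hypermethylated) for
positive deltas and ``maternal`` otherwise.  Biparental samples are never
part of the test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_qvalues, pooled_region_mean
from .config import PipelineConfig
from .model import DMRCall, GeneAnnotation, GenomicInterval, MethylomeSample

log = logging.getLogger(__name__)


@dataclass
class PromoterMethSummary:
    gene_id: str
    sample_id: str
    window: GenomicInterval
    mean_meth_percent: float | None
    n_cpgs: int
    total_reads: int


def promoter_window(
    gene: GeneAnnotation,
    transcript_id: str | None = None,
    flank_bp: int = 500,
) -> GenomicInterval:
    """Window [TSS - flank, TSS + flank) in 0-based coordinates, clipped at 0."""
    tss = gene.tss if transcript_id is None else gene.transcript(transcript_id).tss
    start = max(0, tss - flank_bp)
    return GenomicInterval(gene.chrom, start, tss + flank_bp)


def summarize_promoter(
    sample: MethylomeSample,
    gene: GeneAnnotation,
    window: GenomicInterval,
    config: PipelineConfig,
) -> PromoterMethSummary:
    mean, n_cpgs, reads = pooled_region_mean(
        sample, window, config.min_cov_per_cpg, config.min_cpgs_per_region
    )
    return PromoterMethSummary(gene.gene_id, sample.sample_id, window, mean, n_cpgs, reads)


def _cpg_levels(sample: MethylomeSample, window: GenomicInterval, min_cov: int) -> np.ndarray:
    """Per-CpG methylation fractions for informative CpGs in a window."""
    meth, unmeth = sample.region_counts(window)
    total = meth + unmeth
    keep = total >= min_cov
    if not keep.any():
        return np.empty(0)
    return meth[keep] / total[keep]


def test_promoter(
    ag_samples: list[MethylomeSample],
    pg_samples: list[MethylomeSample],
    window: GenomicInterval,
    config: PipelineConfig,
    mode: str | None = None,
) -> tuple[float, float] | None:
    """Test one promoter window; returns (two-sided p, delta_pp) or None (skipped).

    delta_pp is mean(AG per-sample means) - mean(PG per-sample means), in
    percentage points, regardless of mode.  A gene is skipped when fewer
    than 2 samples per group have an informative summary.
    """
    mode = mode or config.dmr_test_mode
    ag_means, pg_means = [], []
    ag_pool, pg_pool = [], []
    for sample, means, pool in [(s, ag_means, ag_pool) for s in ag_samples] + [
        (s, pg_means, pg_pool) for s in pg_samples
    ]:
        m, n, _ = pooled_region_mean(
            sample, window, config.min_cov_per_cpg, config.min_cpgs_per_region
        )
        if m is not None:
            means.append(m)
            pool.append(_cpg_levels(sample, window, config.min_cov_per_cpg))
    if len(ag_means) < 2 or len(pg_means) < 2:
        return None
    delta_pp = float(np.mean(ag_means) - np.mean(pg_means))

    if mode == "sample_mean":
        res = stats.mannwhitneyu(ag_means, pg_means, alternative="two-sided", method="exact")
        return float(res.pvalue), delta_pp
    # cpg_level: pool per-sample per-CpG fractions; midranks + normal
    # approximation with continuity correction once exact enumeration
    # would exceed ~1e6 partitions (scipy switches automatically under ties)
    a = np.concatenate(ag_pool)
    b = np.concatenate(pg_pool)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.pvalue), delta_pp


def call_promoter_dmrs(
    gene_tests: dict[str, tuple[GenomicInterval, float, float]],
    config: PipelineConfig,
    mode: str | None = None,
) -> list[DMRCall]:
    """BH over all tested promoters; call iff q <= alpha and |delta| >= min delta.

    ``gene_tests`` maps gene_id -> (window, p_value, delta_pp) over the
    expressed-gene universe.
    """
    mode = mode or config.dmr_test_mode
    if not gene_tests:
        log.warning("no promoters tested; returning no DMR calls")
        return []
    genes = sorted(gene_tests)
    pvals = np.array([gene_tests[g][1] for g in genes])
    qvals = bh_qvalues(pvals)
    calls = []
    for g, q in zip(genes, qvals):
        window, p, delta = gene_tests[g]
        if q <= config.dmr_alpha and abs(delta) >= config.dmr_min_delta_pp:
            calls.append(
                DMRCall(
                    gene_id=g,
                    window=window,
                    direction="paternal" if delta > 0 else "maternal",
                    delta_pp=delta,
                    p_value=p,
                    q_value=float(q),
                    test_mode=mode,
                )
            )
    return calls


def dmr_calls_table(calls: list[DMRCall]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": c.gene_id,
            "chrom": c.window.chrom,
            "start": c.window.start,
            "end": c.window.end,
            "direction": c.direction,
            "delta_pp": round(c.delta_pp, 4),
            "p_value": c.p_value,
            "q_value": c.q_value,
            "test_mode": c.test_mode,
        }
        for c in calls
    ]
    cols = ["gene_id", "chrom", "start", "end", "direction", "delta_pp", "p_value", "q_value", "test_mode"]
    return pd.DataFrame(rows, columns=cols)


def run_promoter_stage(
    ag_samples: list[MethylomeSample],
    pg_samples: list[MethylomeSample],
    annotation: dict[str, GeneAnnotation],
    expressed_genes: set[str] | None,
    config: PipelineConfig,
) -> tuple[list[DMRCall], pd.DataFrame]:
    """Test every expressed gene's promoter and call DMRs.

    Returns the calls plus a per-gene table of all tests (for FDR audit).
    """
    universe = set(annotation) if expressed_genes is None else (set(annotation) & expressed_genes)
    tests: dict[str, tuple[GenomicInterval, float, float]] = {}
    skipped = 0
    for gene_id in sorted(universe):
        gene = annotation[gene_id]
        window = promoter_window(gene, flank_bp=config.promoter_flank_bp)
        res = test_promoter(ag_samples, pg_samples, window, config)
        if res is None:
            skipped += 1
            continue
        tests[gene_id] = (window, res[0], res[1])
    if skipped:
        log.info("promoter stage: %d genes skipped (insufficient informative samples)", skipped)
    calls = call_promoter_dmrs(tests, config)
    table = pd.DataFrame(
        [
            {
                "gene_id": g,
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "p_value": p,
                "delta_pp": round(d, 4),
            }
            for g, (w, p, d) in sorted(tests.items())
        ]
    )
    if len(table):
        table["q_value"] = bh_qvalues(table["p_value"].to_numpy())
    return calls, table
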