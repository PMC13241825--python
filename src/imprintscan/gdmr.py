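"""Germline DMR scan: sperm-vs-oocyte methylation in sliding 1-kb windows.

The scan region is anchored on genes of interest and extended by a flank
(200 kb by default), tiled into non-overlapping 1-kb windows.  Each
window's per-sample pooled methylation is compared between sperm and
oocyte by an exact permutation test on |difference of group means|, with
BH control over all tested windows.  With 4 sperm vs 3 oocyte samples
the minimum attainable p is 1/C(7,3) = 1/35, so the attainable FDR floor
depends on the size of the testing universe; the universe actually used
is reported alongside the calls.

A germ-significant window is a germline *candidate* only if the
difference persists in uniparental hESCs with concordant direction
(oocyte-methylated <-> PG-hypermethylated); otherwise it is
germline-non-persistent.  Promoter DMRs in uniparental cells that overlap
no germ-significant window are secondary DMRs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import bh_qvalues, permutation_test, pooled_region_mean
from .config import PipelineConfig
from .model import DMRCall, GeneAnnotation, GenomicInterval, MethylomeSample

log = logging.getLogger(__name__)


@dataclass
class ScanWindow:
    interval: GenomicInterval
    sperm_values: list[float] = field(default_factory=list)
    oocyte_values: list[float] = field(default_factory=list)
    statistic: float | None = None
    p_perm: float | None = None
    q: float | None = None


@dataclass
class GdmrCall:
    window: GenomicInterval
    germ_direction: str  # sperm_methylated | oocyte_methylated
    delta_pp: float  # sperm mean - oocyte mean
    p_perm: float
    q: float
    persistent: bool = False
    persistence_p: float | None = None
    origin_class: str = "none"  # germline_candidate | germline_non_persistent | secondary | none


def make_scan_region(
    anchor_genes: list[str],
    flank_bp: int,
    annotation: dict[str, GeneAnnotation],
) -> GenomicInterval:
    """Span of the anchor genes' transcripts, extended by ``flank_bp``, clipped at 0."""
    missing = [g for g in anchor_genes if g not in annotation]
    if missing:
        raise KeyError(f"anchor gene(s) not in annotation: {missing}")
    ivs = [t.interval for g in anchor_genes for t in annotation[g].transcripts]
    chroms = {iv.chrom for iv in ivs}
    if len(chroms) != 1:
        raise ValueError(f"anchors span multiple chromosomes: {sorted(chroms)}")
    start = max(0, min(iv.start for iv in ivs) - flank_bp)
    end = max(iv.end for iv in ivs) + flank_bp
    return GenomicInterval(chroms.pop(), start, end)


def make_windows(region: GenomicInterval, window_bp: int) -> list[GenomicInterval]:
    """Non-overlapping genome-grid tiles [k*w, (k+1)*w) intersected with the region.

    Tiles are anchored at multiples of the window size, so the same
    genomic window is produced regardless of where the region starts;
    the first and last tiles may be short.
    """
    out = []
    k = region.start // window_bp
    while k * window_bp < region.end:
        start = max(region.start, k * window_bp)
        end = min(region.end, (k + 1) * window_bp)
        out.append(GenomicInterval(region.chrom, start, end))
        k += 1
    return out


def _group_window_values(
    samples: list[MethylomeSample],
    window: GenomicInterval,
    config: PipelineConfig,
) -> list[float]:
    vals = []
    for s in samples:
        m, _n, _r = pooled_region_mean(
            s, window, config.min_cov_per_cpg, config.min_cpgs_per_region
        )
        if m is not None:
            vals.append(m)
    return vals


def scan_windows(
    sperm: list[MethylomeSample],
    oocyte: list[MethylomeSample],
    region: GenomicInterval,
    config: PipelineConfig,
    max_exact: int = 100_000,
    rng: np.random.Generator | None = None,
) -> list[ScanWindow]:
    """Permutation-test every informative window in the region.

    Windows with fewer than 2 informative samples in either group are
    skipped (returned with p None) and excluded from the FDR universe.
    """
    windows = []
    for iv in make_windows(region, config.gdmr_window_bp):
        w = ScanWindow(interval=iv)
        w.sperm_values = _group_window_values(sperm, iv, config)
        w.oocyte_values = _group_window_values(oocyte, iv, config)
        if len(w.sperm_values) >= 2 and len(w.oocyte_values) >= 2:
            w.statistic = abs(float(np.mean(w.sperm_values)) - float(np.mean(w.oocyte_values)))
            w.p_perm = permutation_test(
                np.array(w.sperm_values), np.array(w.oocyte_values),
                max_exact=max_exact, rng=rng,
            )
        windows.append(w)
    tested = [w for w in windows if w.p_perm is not None]
    if tested:
        qs = bh_qvalues(np.array([w.p_perm for w in tested]))
        for w, q in zip(tested, qs):
            w.q = float(q)
    log.info("gdmr scan: %d/%d windows tested", len(tested), len(windows))
    return windows


def call_gdmrs(windows: list[ScanWindow], config: PipelineConfig) -> list[GdmrCall]:
    """Germ-significant windows: q <= alpha AND |delta| >= minimum delta."""
    calls = []
    for w in windows:
        if w.p_perm is None or w.q is None:
            continue
        delta = float(np.mean(w.sperm_values)) - float(np.mean(w.oocyte_values))
        if w.q <= config.dmr_alpha and abs(delta) >= config.dmr_min_delta_pp:
            calls.append(
                GdmrCall(
                    window=w.interval,
                    germ_direction="sperm_methylated" if delta > 0 else "oocyte_methylated",
                    delta_pp=delta,
                    p_perm=w.p_perm,
                    q=w.q,
                )
            )
    return calls


def persistence_check(
    call: GdmrCall,
    ag_samples: list[MethylomeSample],
    pg_samples: list[MethylomeSample],
    config: PipelineConfig,
    alpha: float = 0.05,
    max_exact: int = 100_000,
    rng: np.random.Generator | None = None,
) -> GdmrCall:
    """Test whether a germ DMR persists in uniparental hESCs, concordantly.

    Concordance: an oocyte-methylated window should be PG-hypermethylated
    (maternal genome), a sperm-methylated one AG-hypermethylated.
    """
    ag_vals = _group_window_values(ag_samples, call.window, config)
    pg_vals = _group_window_values(pg_samples, call.window, config)
    call.persistent = False
    call.persistence_p = None
    if len(ag_vals) >= 2 and len(pg_vals) >= 2:
        p = permutation_test(np.array(ag_vals), np.array(pg_vals), max_exact=max_exact, rng=rng)
        call.persistence_p = p
        delta_uni = float(np.mean(ag_vals)) - float(np.mean(pg_vals))
        concordant = (
            (call.germ_direction == "sperm_methylated" and delta_uni > 0)
            or (call.germ_direction == "oocyte_methylated" and delta_uni < 0)
        )
        call.persistent = p <= alpha and concordant
    call.origin_class = "germline_candidate" if call.persistent else "germline_non_persistent"
    return call


def classify_dmr_origin(
    promoter_calls: list[DMRCall],
    gdmr_calls: list[GdmrCall],
) -> dict[str, str]:
    """Per promoter DMR: germline-derived vs secondary.

    A uniparental promoter DMR overlapping a concordant germ-significant
    window (paternal DMR <-> sperm-methylated; maternal <-> oocyte) is
    germline-derived; otherwise it is a secondary DMR.
    """
    out = {}
    for call in promoter_calls:
        germ_dir = "sperm_methylated" if call.direction == "paternal" else "oocyte_methylated"
        hit = any(
            g.window.overlaps(call.window) and g.germ_direction == germ_dir
            for g in gdmr_calls
        )
        out[call.gene_id] = "germline_derived" if hit else "secondary"
    return out


def gdmr_table(calls: list[GdmrCall]) -> pd.DataFrame:
    rows = [
        {
            "chrom": c.window.chrom,
            "start": c.window.start,
            "end": c.window.end,
            "germ_direction": c.germ_direction,
            "delta_pp": round(c.delta_pp, 4),
            "p_perm": c.p_perm,
            "q_value": c.q,
            "persistent": c.persistent,
            "persistence_p": c.persistence_p,
            "origin_class": c.origin_class,
        }
        for c in calls
    ]
    cols = [
        "chrom", "start", "end", "germ_direction", "delta_pp",
        "p_perm", "q_value", "persistent", "persistence_p", "origin_class",
    ]
    return pd.DataFrame(rows, columns=cols)
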