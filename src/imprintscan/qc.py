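"""Sample QC against a registry of known imprinted DMRs.

A sample's methylome is scored at each known DMR; a DMR behaves "normally"
when its pooled methylation lies in the 30-70% band expected of a
parent-of-origin-methylated region assayed in diploid cells.  A sample is
kept only if at least half of the assessable DMRs are normal — cultured
pluripotent lines frequently erode imprints (loss of imprinting), and this
filter removes heavily eroded samples before any downstream comparison.

The aberration report reproduces the grouping seen across uniparental
lines: some known DMRs become hypermethylated in every origin group yet
retain the androgenetic-vs-parthenogenetic difference (partial erosion on
one allele), others equalise completely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import pooled_region_mean
from .config import PipelineConfig
from .model import GenomicInterval, KnownDmr, MethylomeSample


@dataclass
class DmrStatus:
    sample_id: str
    dmr_name: str
    mean_meth_percent: float | None
    status: str  # normal | hyper | hypo | no_data


class QcError(RuntimeError):
    """Raised when a sample cannot be assessed (no DMR has data)."""


def mean_meth_in_region(
    sample: MethylomeSample,
    region: GenomicInterval,
    min_cov: int,
    min_cpgs: int = 3,
) -> float | None:
    """Pooled mean methylation (%) over informative CpGs, or None (no data)."""
    mean, _n, _reads = pooled_region_mean(sample, region, min_cov, min_cpgs)
    return mean


def classify_dmr_status(mean_percent: float, config: PipelineConfig) -> str:
    lo, hi = config.qc_normal_range
    if mean_percent < lo:
        return "hypo"
    if mean_percent > hi:
        return "hyper"
    return "normal"


def dmr_statuses(
    sample: MethylomeSample,
    registry: list[KnownDmr],
    config: PipelineConfig,
) -> list[DmrStatus]:
    out = []
    for dmr in registry:
        mean = mean_meth_in_region(
            sample, dmr.interval, config.min_cov_per_cpg, config.min_cpgs_per_region
        )
        status = "no_data" if mean is None else classify_dmr_status(mean, config)
        out.append(DmrStatus(sample.sample_id, dmr.name, mean, status))
    return out


def qc_pass(
    sample: MethylomeSample,
    registry: list[KnownDmr],
    config: PipelineConfig,
) -> tuple[bool, list[DmrStatus]]:
    """Inclusion filter: pass iff >= qc_min_fraction of assessable DMRs are normal.

    DMRs without data are excluded from the denominator.  Raises
    :class:`QcError` when no DMR is assessable.
    """
    if not registry:
        raise ValueError("registry must be non-empty")
    statuses = dmr_statuses(sample, registry, config)
    with_data = [s for s in statuses if s.status != "no_data"]
    if not with_data:
        raise QcError(f"sample {sample.sample_id}: no known DMR has data")
    n_normal = sum(s.status == "normal" for s in with_data)
    return (n_normal / len(with_data)) >= config.qc_min_fraction, statuses


def qc_report(
    samples: list[MethylomeSample],
    registry: list[KnownDmr],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Per-sample QC table: one row per (sample, DMR) plus a pass flag."""
    rows = []
    for sample in samples:
        try:
            passed, statuses = qc_pass(sample, registry, config)
        except QcError:
            passed, statuses = False, dmr_statuses(sample, registry, config)
        for s in statuses:
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "dmr": s.dmr_name,
                    "mean_meth_percent": (
                        round(s.mean_meth_percent, 4) if s.mean_meth_percent is not None else np.nan
                    ),
                    "status": s.status,
                    "qc_pass": passed,
                }
            )
    return pd.DataFrame(rows)


def aberration_report(
    samples: list[MethylomeSample],
    registry: list[KnownDmr],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Group known DMRs by their behaviour across origin groups.

    A known DMR whose biparental mean exceeds the upper bound of the
    normal band is aberrantly hypermethylated (culture-induced gain on
    the normally unmethylated allele).  Such a DMR is labelled
    ``retained-difference`` when the AG-PG delta still exceeds
    ``dmr_min_delta_pp`` (the parental difference survives the erosion),
    otherwise ``uniform-hyper`` (the difference is lost in the
    uniparental cells too).  All other DMRs are ``normal-behaviour``.
    Without biparental samples, the trigger falls back to both
    uniparental groups being hypermethylated.
    """
    groups: dict[str, list[MethylomeSample]] = {}
    for s in samples:
        groups.setdefault(s.origin, []).append(s)
    ag = groups.get("androgenetic", [])
    pg = groups.get("parthenogenetic", [])
    if len(ag) < 2 or len(pg) < 2:
        raise ValueError("aberration report requires >= 2 androgenetic and >= 2 parthenogenetic samples")
    _, hi = config.qc_normal_range

    def group_mean(dmr: KnownDmr, members: list[MethylomeSample]) -> float | None:
        vals = [
            mean_meth_in_region(s, dmr.interval, config.min_cov_per_cpg, config.min_cpgs_per_region)
            for s in members
        ]
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    rows = []
    for dmr in registry:
        means = {origin: group_mean(dmr, members) for origin, members in groups.items()}
        ag_m, pg_m = means.get("androgenetic"), means.get("parthenogenetic")
        bi_m = means.get("biparental")
        if ag_m is None or pg_m is None:
            aberrant = False
        elif bi_m is not None:
            aberrant = bi_m > hi
        else:
            aberrant = ag_m > hi and pg_m > hi
        if aberrant:
            label = (
                "retained-difference"
                if abs(ag_m - pg_m) >= config.dmr_min_delta_pp
                else "uniform-hyper"
            )
        else:
            label = "normal-behaviour"
        row = {"dmr": dmr.name, "germline_origin": dmr.germline_origin, "group": label}
        for origin, val in means.items():
            row[f"mean_{origin}"] = round(val, 4) if val is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
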