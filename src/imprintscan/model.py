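"""Shared genomic data model.

Coordinates are 0-based half-open internally.  Bismark cytosine-report
positions (1-based) are converted on ingest; see :mod:`imprintscan.io`.
Methylation levels are fractions in [0, 1] internally and percent (0-100)
at every reporting boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

ORIGINS = frozenset({"androgenetic", "parthenogenetic", "biparental", "sperm", "oocyte"})
STAGES = frozenset({"ESC", "NPC", "germ", "other"})


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_pos(self, chrom: str, pos0: int) -> bool:
        return chrom == self.chrom and self.start <= pos0 < self.end


@dataclass
class MethylomeSample:
    """Per-CpG methylated/unmethylated counts for one labelled sample.

    ``calls`` is a DataFrame with columns ``chrom`` (str), ``pos`` (int,
    0-based), ``meth`` (int), ``unmeth`` (int), unique on (chrom, pos).
    """

    sample_id: str
    origin: str
    stage: str
    calls: pd.DataFrame
    dyads_merged: bool = False

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}; expected one of {sorted(ORIGINS)}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {sorted(STAGES)}")
        required = {"chrom", "pos", "meth", "unmeth"}
        missing = required - set(self.calls.columns)
        if missing:
            raise ValueError(f"calls missing columns {sorted(missing)}")
        if self.calls.duplicated(["chrom", "pos"]).any():
            raise ValueError(f"duplicate (chrom, pos) in sample {self.sample_id}")
        if (self.calls["meth"] < 0).any() or (self.calls["unmeth"] < 0).any():
            raise ValueError("negative methylation counts")

    @property
    def n_cpgs(self) -> int:
        return len(self.calls)

    def _index(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-chromosome position-sorted count arrays, built lazily."""
        cached = getattr(self, "_chrom_index", None)
        if cached is None:
            cached = {}
            for chrom, sub in self.calls.groupby("chrom", sort=False):
                order = np.argsort(sub["pos"].to_numpy(), kind="stable")
                cached[chrom] = (
                    sub["pos"].to_numpy()[order],
                    sub["meth"].to_numpy()[order],
                    sub["unmeth"].to_numpy()[order],
                )
            object.__setattr__(self, "_chrom_index", cached)
        return cached

    def region_counts(self, region: GenomicInterval) -> tuple[np.ndarray, np.ndarray]:
        """(meth, unmeth) count arrays for CpGs inside ``region``."""
        idx = self._index().get(region.chrom)
        if idx is None:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        pos, meth, unmeth = idx
        lo = np.searchsorted(pos, region.start, side="left")
        hi = np.searchsorted(pos, region.end, side="left")
        return meth[lo:hi], unmeth[lo:hi]

    def in_region(self, region: GenomicInterval) -> pd.DataFrame:
        """Calls falling inside ``region`` (0-based half-open)."""
        c = self.calls
        mask = (
            (c["chrom"] == region.chrom)
            & (c["pos"] >= region.start)
            & (c["pos"] < region.end)
        )
        return c.loc[mask]


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    interval: GenomicInterval

    @property
    def tss(self) -> int:
        """Strand-aware TSS, 0-based: leftmost base on +, rightmost on -."""
        if self.interval.strand == "+":
            return self.interval.start
        if self.interval.strand == "-":
            return self.interval.end - 1
        raise ValueError(f"transcript {self.transcript_id} has no strand")


@dataclass
class GeneAnnotation:
    gene_id: str
    gene_name: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].interval.chrom

    @property
    def tss(self) -> int:
        """Representative TSS: the 5'-most among transcripts (first listed wins ties)."""
        return self.transcripts[0].tss

    def transcript(self, transcript_id: str) -> Transcript:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(f"unknown transcript {transcript_id!r} in gene {self.gene_id}")


@dataclass(frozen=True)
class KnownDmr:
    """A registry entry for a known imprinted DMR."""

    name: str
    interval: GenomicInterval
    germline_origin: str  # paternal | maternal
    notes: str = ""

    def __post_init__(self) -> None:
        if self.germline_origin not in {"paternal", "maternal"}:
            raise ValueError(f"origin must be paternal/maternal, got {self.germline_origin!r}")


@dataclass
class DMRCall:
    """A called differentially methylated promoter."""

    gene_id: str
    window: GenomicInterval
    direction: str  # paternal (AG-hypermethylated) | maternal
    delta_pp: float  # AG mean - PG mean, percentage points
    p_value: float
    q_value: float
    test_mode: str

    def __post_init__(self) -> None:
        expected = "paternal" if self.delta_pp > 0 else "maternal"
        if self.direction != expected:
            raise ValueError(
                f"direction {self.direction} inconsistent with delta {self.delta_pp:+.1f}pp"
            )


@dataclass
class SampleManifest:
    """Maps sample ids to (origin, stage) labels and input file paths."""

    entries: dict[str, dict]

    def __post_init__(self) -> None:
        for sid, entry in self.entries.items():
            if entry.get("origin") not in ORIGINS:
                raise ValueError(f"sample {sid}: bad origin {entry.get('origin')!r}")
            if entry.get("stage") not in STAGES:
                raise ValueError(f"sample {sid}: bad stage {entry.get('stage')!r}")

    def sample_ids(self) -> list[str]:
        return list(self.entries)

    def by_group(self, origin: str, stage: Optional[str] = None) -> list[str]:
        return [
            sid
            for sid, e in self.entries.items()
            if e["origin"] == origin and (stage is None or e["stage"] == stage)
        ]
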