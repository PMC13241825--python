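"""Pipeline configuration: every threshold the analysis uses, in one place.

Defaults follow the published analysis conventions for this kind of study:
promoter = TSS +/- 500 bp; a known DMR is "normal" at 30-70% methylation;
a sample passes QC when at least half of assessable known DMRs are normal;
allelic ratio < 0.15 is monoallelic, 0.15-0.3 partially monoallelic;
"> 5 reads" per SNP (>= 6), or >= 20 in stringent mode; germline scan uses
1-kb windows over anchor span +/- 200 kb; cluster search radius 500 kb
(a 1-Mb window around each anchor TSS).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml


@dataclass
class PipelineConfig:
    promoter_flank_bp: int = 500
    qc_normal_range: tuple[float, float] = (30.0, 70.0)  # percent, inclusive
    qc_min_fraction: float = 0.5
    dmr_alpha: float = 0.05
    dmr_min_delta_pp: float = 25.0
    min_cpgs_per_region: int = 3
    min_cov_per_cpg: int = 5
    expressed_tpm: float = 1.0
    ase_min_reads: int = 6  # "> 5 reads"
    ase_stringent_reads: int = 20
    ase_mono: float = 0.15
    ase_partial: float = 0.3
    gdmr_window_bp: int = 1000
    gdmr_flank_bp: int = 200_000
    cluster_radius_bp: int = 500_000
    merge_dyads: bool = True
    dmr_test_mode: str = "cpg_level"  # or "sample_mean"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.qc_normal_range = tuple(self.qc_normal_range)  # type: ignore[assignment]
        lo, hi = self.qc_normal_range
        if not (0 <= lo <= hi <= 100):
            raise ValueError(f"qc_normal_range must lie in [0, 100]: {self.qc_normal_range}")
        if not (0 < self.ase_mono < self.ase_partial <= 0.5):
            raise ValueError("require 0 < ase_mono < ase_partial <= 0.5")
        for name in (
            "promoter_flank_bp",
            "qc_min_fraction",
            "dmr_alpha",
            "dmr_min_delta_pp",
            "min_cpgs_per_region",
            "min_cov_per_cpg",
            "expressed_tpm",
            "ase_min_reads",
            "ase_stringent_reads",
            "gdmr_window_bp",
            "gdmr_flank_bp",
            "cluster_radius_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dmr_test_mode not in {"cpg_level", "sample_mean"}:
            raise ValueError(f"unknown dmr_test_mode {self.dmr_test_mode!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["qc_normal_range"] = list(self.qc_normal_range)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
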