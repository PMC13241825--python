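"""End-to-end orchestration: qc -> expression -> promoter-dmr -> ase -> gdmr -> integrate.

The QC gate is applied to biparental samples only: the known-DMR filter
assumes a diploid biparental genome where an imprinted DMR sits near 50%
methylation, a premise that does not hold for uniparental genomes (a
paternally methylated DMR is expected fully methylated in androgenetic
cells).  Failing samples are excluded with a logged reason and the run
continues.

Promoter DMRs are tested on androgenetic-vs-parthenogenetic samples
pooled across stages (imprinted promoter methylation is stable between
ESC and NPC); differential expression is tested per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ase import ase_summary_table
from .config import PipelineConfig
from .expression import classify_imprinted_expression, expressed_filter, nb_exact_test, normalize
from .gdmr import (
    GdmrCall,
    call_gdmrs,
    classify_dmr_origin,
    gdmr_table,
    make_scan_region,
    persistence_check,
    scan_windows,
)
from .integrate import assemble_candidates
from .io import write_candidate_table
from .model import DMRCall, GeneAnnotation, KnownDmr, MethylomeSample
from .promoter import dmr_calls_table, run_promoter_stage
from .qc import QcError, qc_pass, qc_report

log = logging.getLogger(__name__)


@dataclass
class PipelineInputs:
    methylomes: list[MethylomeSample]
    counts: dict[str, pd.DataFrame]  # stage -> genes x samples
    annotation: dict[str, GeneAnnotation]
    gene_lengths: pd.Series | None = None
    ase_records: pd.DataFrame | None = None
    germ_methylomes: list[MethylomeSample] = field(default_factory=list)
    registry: list[KnownDmr] = field(default_factory=list)
    gdmr_anchor_genes: list[str] = field(default_factory=list)


@dataclass
class RunResult:
    candidates: pd.DataFrame
    dmr_only: pd.DataFrame
    qc: pd.DataFrame
    excluded_samples: list[str]
    promoter_tests: pd.DataFrame
    dmr_calls: list[DMRCall]
    expression: dict[str, pd.DataFrame]
    ase_summary: pd.DataFrame
    gdmr_calls: list[GdmrCall]
    dmr_origin: dict[str, str]
    config: PipelineConfig
    seed: int


def run_all(inputs: PipelineInputs, config: PipelineConfig, seed: int | None = None) -> RunResult:
    seed = config.rng_seed if seed is None else seed
    rng = np.random.default_rng(seed)

    # --- QC gate (biparental samples only; see module docstring)
    excluded: list[str] = []
    qc_table = pd.DataFrame()
    if inputs.registry:
        qc_table = qc_report(inputs.methylomes, inputs.registry, config)
        for s in inputs.methylomes:
            if s.origin != "biparental":
                continue
            try:
                passed, _ = qc_pass(s, inputs.registry, config)
            except QcError:
                passed = False
            if not passed:
                log.warning("sample %s failed known-DMR QC; excluded", s.sample_id)
                excluded.append(s.sample_id)
    methylomes = [s for s in inputs.methylomes if s.sample_id not in excluded]

    # --- expression per stage
    expression: dict[str, pd.DataFrame] = {}
    expressed_union: set[str] = set()
    for stage, counts in sorted(inputs.counts.items()):
        counts = counts.drop(columns=[c for c in excluded if c in counts.columns])
        by_origin = {
            origin: [s.sample_id for s in methylomes if s.stage == stage and s.origin == origin]
            for origin in ("androgenetic", "parthenogenetic")
        }
        ag = [c for c in counts.columns if c in by_origin["androgenetic"]]
        pg = [c for c in counts.columns if c in by_origin["parthenogenetic"]]
        if len(ag) < 2 or len(pg) < 2:
            # fall back to name-based grouping when methylome and count
            # sample ids differ
            ag = [c for c in counts.columns if c.startswith("AN")]
            pg = [c for c in counts.columns if c.startswith("PA")]
        norm = normalize(counts, inputs.gene_lengths)
        universe = expressed_filter(norm, list(counts.columns), config)
        tests = nb_exact_test(counts, ag, pg)
        expression[stage] = classify_imprinted_expression(tests, universe, config, stage=stage)
        expressed_union |= universe

    # --- promoter DMRs: AG vs PG pooled across stages
    ag_samples = [s for s in methylomes if s.origin == "androgenetic"]
    pg_samples = [s for s in methylomes if s.origin == "parthenogenetic"]
    dmr_calls, promoter_tests = run_promoter_stage(
        ag_samples, pg_samples, inputs.annotation, expressed_union, config
    )

    # --- ASE
    if inputs.ase_records is not None and len(inputs.ase_records):
        ase_summary = ase_summary_table(inputs.ase_records, config)
    else:
        ase_summary = pd.DataFrame(columns=["gene_id", "support", "isoform_specific"])

    # --- germline scan
    gdmr_calls: list[GdmrCall] = []
    if inputs.germ_methylomes and inputs.gdmr_anchor_genes:
        sperm = [s for s in inputs.germ_methylomes if s.origin == "sperm"]
        oocyte = [s for s in inputs.germ_methylomes if s.origin == "oocyte"]
        region = make_scan_region(inputs.gdmr_anchor_genes, config.gdmr_flank_bp, inputs.annotation)
        windows = scan_windows(sperm, oocyte, region, config, rng=rng)
        gdmr_calls = call_gdmrs(windows, config)
        ag_esc = [s for s in ag_samples if s.stage == "ESC"] or ag_samples
        pg_esc = [s for s in pg_samples if s.stage == "ESC"] or pg_samples
        for call in gdmr_calls:
            persistence_check(call, ag_esc, pg_esc, config, rng=rng)
    dmr_origin = classify_dmr_origin(dmr_calls, gdmr_calls)

    # --- integration
    candidates, dmr_only = assemble_candidates(
        dmr_calls, expression, ase_summary, gdmr_calls, inputs.annotation, config
    )
    return RunResult(
        candidates=candidates,
        dmr_only=dmr_only,
        qc=qc_table,
        excluded_samples=excluded,
        promoter_tests=promoter_tests,
        dmr_calls=dmr_calls,
        expression=expression,
        ase_summary=ase_summary,
        gdmr_calls=gdmr_calls,
        dmr_origin=dmr_origin,
        config=config,
        seed=seed,
    )


def write_outputs(result: RunResult, outdir) -> dict[str, str]:
    """Write all stage tables plus a machine-readable run manifest.

    Returns path -> sha256 of every written file.  Output content is a
    pure function of (inputs, config, seed); the manifest additionally
    records the configuration snapshot so a run can be reproduced.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_candidate_table(result.candidates, outdir / "candidates.tsv")
    write_candidate_table(result.dmr_only, outdir / "dmr_only.tsv")
    result.qc.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    result.promoter_tests.to_csv(outdir / "promoter_tests.tsv", sep="\t", index=False)
    dmr_calls_table(result.dmr_calls).to_csv(outdir / "dmr_calls.tsv", sep="\t", index=False)
    for stage, table in result.expression.items():
        table.to_csv(outdir / f"expression_{stage}.tsv", sep="\t", index_label="gene_id")
    result.ase_summary.to_csv(outdir / "ase_summary.tsv", sep="\t", index=False)
    gdmr_table(result.gdmr_calls).to_csv(outdir / "gdmr_calls.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"gene_id": g, "origin_class": c} for g, c in sorted(result.dmr_origin.items())]
    ).to_csv(outdir / "dmr_origin.tsv", sep="\t", index=False)

    checksums = {}
    for path in sorted(outdir.glob("*.tsv")):
        checksums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {
        "tool": "imprintscan",
        "version": __version__,
        "seed": result.seed,
        "config": result.config.to_dict(),
        "excluded_samples": result.excluded_samples,
        "checksums": checksums,
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return checksums
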