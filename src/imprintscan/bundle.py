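"""Assemble pipeline inputs: from a simulation scenario or from files on disk.

``simulate_inputs`` builds an in-memory :class:`PipelineInputs` directly;
``simulate_to_dir`` writes the same data as files (Bismark coverage,
count TSVs, ASE TSV, annotation, registry BED, YAML manifest) so the CLI
``run-all`` can consume them, and ``load_inputs`` reads such a manifest
back.  The two routes produce identical analysis inputs for the same
scenario and seed.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .io import (
    read_ase_table,
    read_counts_matrix,
    read_cytosine_report,
    read_dmr_registry,
    read_gene_annotation,
    write_ase_table,
    write_counts_matrix,
    write_coverage,
)
from .model import GeneAnnotation, MethylomeSample
from .pipeline import PipelineInputs
from .simulate import (
    SimulationScenario,
    gene_lengths,
    ground_truth,
    simulate_annotation,
    simulate_ase,
    simulate_counts,
    simulate_germ,
    simulate_methylomes,
    synthetic_registry,
)


def simulate_inputs(
    scenario: SimulationScenario, seed: int
) -> tuple[PipelineInputs, dict[str, pd.DataFrame]]:
    """In-memory inputs plus the ground-truth ledgers ('genes', 'germ_windows')."""
    methylomes, truth = simulate_methylomes(scenario, seed)
    germ, germ_truth = simulate_germ(scenario, seed)
    counts, _ = simulate_counts(scenario, seed)
    ase_df, _ = simulate_ase(scenario, seed)
    annotation = simulate_annotation(scenario)
    inputs = PipelineInputs(
        methylomes=methylomes,
        counts=counts,
        annotation=annotation,
        gene_lengths=gene_lengths(scenario),
        ase_records=ase_df,
        germ_methylomes=germ,
        registry=synthetic_registry(scenario),
        gdmr_anchor_genes=[f"G{i:04d}" for i in scenario.germ_anchor_genes],
    )
    return inputs, {"genes": truth, "germ_windows": germ_truth}


def _annotation_to_bed12(annotation: dict[str, GeneAnnotation], path: Path) -> None:
    rows = []
    for gene in annotation.values():
        for t in gene.transcripts:
            iv = t.interval
            rows.append(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{gene.gene_id}|{t.transcript_id}"
                f"\t0\t{iv.strand}"
            )
    path.write_text("\n".join(rows) + "\n")


def _registry_to_bed(registry, path: Path) -> None:
    rows = [
        f"{d.interval.chrom}\t{d.interval.start}\t{d.interval.end}\t{d.name}"
        f"\t0\t.\t{d.germline_origin}\t{d.notes}"
        for d in registry
    ]
    path.write_text("\n".join(rows) + "\n")


def simulate_to_dir(scenario: SimulationScenario, seed: int, outdir) -> Path:
    """Write a complete simulated dataset + manifest; returns the manifest path."""
    outdir = Path(outdir)
    (outdir / "methylomes").mkdir(parents=True, exist_ok=True)
    inputs, truths = simulate_inputs(scenario, seed)

    samples = {}
    for s in inputs.methylomes + inputs.germ_methylomes:
        rel = f"methylomes/{s.sample_id}.cov"
        write_coverage(s, outdir / rel)
        samples[s.sample_id] = {"origin": s.origin, "stage": s.stage, "methylome": rel}

    counts_entries = {}
    for stage, mat in inputs.counts.items():
        rel = f"counts_{stage}.tsv"
        write_counts_matrix(mat, outdir / rel)
        counts_entries[stage] = rel
    inputs.gene_lengths.rename("length_bp").to_csv(
        outdir / "gene_lengths.tsv", sep="\t", index_label="gene_id"
    )
    write_ase_table(inputs.ase_records, outdir / "ase.tsv")
    _annotation_to_bed12(inputs.annotation, outdir / "annotation.bed")
    _registry_to_bed(inputs.registry, outdir / "registry.bed")
    for name, df in truths.items():
        df.to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)

    manifest = {
        "samples": samples,
        "counts": counts_entries,
        "gene_lengths": "gene_lengths.tsv",
        "ase": "ase.tsv",
        "annotation": {"path": "annotation.bed", "dialect": "BED12"},
        "registry": "registry.bed",
        "gdmr_anchor_genes": inputs.gdmr_anchor_genes,
        "seed": seed,
    }
    manifest_path = outdir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path


def load_inputs(manifest_path) -> PipelineInputs:
    """Load a :class:`PipelineInputs` bundle from a YAML manifest."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)

    methylomes: list[MethylomeSample] = []
    germ: list[MethylomeSample] = []
    for sid, entry in manifest["samples"].items():
        sample = read_cytosine_report(
            root / entry["methylome"],
            dialect=entry.get("dialect", "coverage"),
            sample_id=sid,
            origin=entry["origin"],
            stage=entry["stage"],
        )
        (germ if entry["origin"] in ("sperm", "oocyte") else methylomes).append(sample)

    counts = {
        stage: read_counts_matrix(root / rel) for stage, rel in manifest.get("counts", {}).items()
    }
    lengths = None
    if "gene_lengths" in manifest:
        lengths = pd.read_csv(root / manifest["gene_lengths"], sep="\t", index_col=0)["length_bp"]
    ase_records = read_ase_table(root / manifest["ase"]) if "ase" in manifest else None
    ann = manifest["annotation"]
    annotation = read_gene_annotation(root / ann["path"], dialect=ann["dialect"])
    registry = read_dmr_registry(root / manifest["registry"]) if "registry" in manifest else []
    return PipelineInputs(
        methylomes=methylomes,
        counts=counts,
        annotation=annotation,
        gene_lengths=lengths,
        ase_records=ase_records,
        germ_methylomes=germ,
        registry=registry,
        gdmr_anchor_genes=list(manifest.get("gdmr_anchor_genes", [])),
    )
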