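"""Readers and writers for every external format the pipeline touches.

Dialects
--------
Methylation calls come in two Bismark output dialects:

* ``cytosine_report`` — one row per cytosine: chrom, 1-based pos, strand,
  meth count, unmeth count, context, trinucleotide.  Only CpG-context rows
  are kept; positions are converted to 0-based on ingest.
* ``coverage`` (``.cov``) — chrom, 1-based start, 1-based end, percent
  methylation, meth count, unmeth count.  All rows are CpG by construction.

Gene annotation comes as BED12, a minimal GTF (``gtf_lite``: only gene_id /
transcript_id attributes are parsed), or a 4-column TSS table.

Opposite-strand calls at a CpG dyad (positions p / p+1 on +/-) are merged
by count-summing when ``merge_dyads`` is set, which is standard practice
for CpG-symmetric methylation and raises effective coverage.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (
    GeneAnnotation,
    GenomicInterval,
    KnownDmr,
    MethylomeSample,
    SampleManifest,
    Transcript,
)

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed input line; message carries the offending line number."""


def _merge_dyads(df: pd.DataFrame) -> pd.DataFrame:
    """Sum counts of opposite-strand calls at a CpG dyad onto the + position.

    A call at (chrom, p, '-') is assigned to the dyad anchored at p-1.
    """
    df = df.copy()
    anchor = df["pos"].where(df["strand"] != "-", df["pos"] - 1)
    df["pos"] = anchor
    merged = (
        df.groupby(["chrom", "pos"], as_index=False, sort=True)[["meth", "unmeth"]]
        .sum()
    )
    return merged


def read_cytosine_report(
    path,
    dialect: str,
    *,
    sample_id: str = "sample",
    origin: str = "biparental",
    stage: str = "other",
    merge_dyads: bool = True,
) -> MethylomeSample:
    """Read per-CpG methylation calls from a Bismark-style file.

    Positions are converted from the file's 1-based convention to the
    internal 0-based convention.  In ``cytosine_report`` dialect only
    CpG-context rows are retained.
    """
    path = Path(path)
    if dialect == "cytosine_report":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 6:
                    raise ParseError(f"{path}:{lineno}: expected >= 6 fields, got {len(parts)}")
                chrom, pos, strand, meth, unmeth, context = parts[:6]
                if context != "CpG":
                    continue
                try:
                    rows.append((chrom, int(pos) - 1, strand, int(meth), int(unmeth)))
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
        df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "meth", "unmeth"])
    elif dialect == "coverage":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) != 6:
                    raise ParseError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
                chrom, start1, _end1, _pct, meth, unmeth = parts
                try:
                    rows.append((chrom, int(start1) - 1, ".", int(meth), int(unmeth)))
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
        df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "meth", "unmeth"])
    else:
        raise ValueError(f"unknown methylation dialect {dialect!r}")

    if merge_dyads and len(df):
        df = _merge_dyads(df)
    else:
        df = (
            df.groupby(["chrom", "pos"], as_index=False, sort=True)[["meth", "unmeth"]]
            .sum()
        )
    return MethylomeSample(
        sample_id=sample_id,
        origin=origin,
        stage=stage,
        calls=df.reset_index(drop=True),
        dyads_merged=merge_dyads,
    )


def write_coverage(sample: MethylomeSample, path) -> None:
    """Write calls in Bismark coverage dialect (positions back to 1-based)."""
    c = sample.calls
    total = c["meth"] + c["unmeth"]
    with np.errstate(invalid="ignore"):
        pct = np.where(total > 0, 100.0 * c["meth"] / total, 0.0)
    out = pd.DataFrame(
        {
            "chrom": c["chrom"],
            "start": c["pos"] + 1,
            "end": c["pos"] + 1,
            "pct": np.round(pct, 6),
            "meth": c["meth"],
            "unmeth": c["unmeth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_counts_matrix(path, manifest: SampleManifest | None = None) -> pd.DataFrame:
    """Read a genes x samples raw-count matrix from delimited text."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated gene_id(s): {dupes}")
    if df.isna().any().any():
        raise ValueError("missing cells in counts matrix")
    if (df.to_numpy() < 0).any():
        raise ValueError("negative counts in matrix")
    if not np.allclose(df.to_numpy(), np.round(df.to_numpy())):
        raise ValueError("non-integer counts in matrix")
    df = df.astype(np.int64)
    if manifest is not None:
        unknown = set(df.columns) - set(manifest.sample_ids())
        if unknown:
            raise ValueError(f"samples in counts header absent from manifest: {sorted(unknown)}")
    return df


def write_counts_matrix(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


ASE_COLUMNS = ["sample_id", "gene_id", "transcript_id", "chrom", "pos", "ref_count", "alt_count"]


def read_ase_table(path) -> pd.DataFrame:
    """Read a per-SNP allele-count table (EpiTyping-compatible columns).

    Returns a DataFrame with ``total`` and ``allelic_ratio`` derived.
    An optional ``cell_type`` column is carried through when present.
    """
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": "string"})
    if df.empty:
        log.warning("ASE table %s is empty", path)
        base = ASE_COLUMNS + ["total", "allelic_ratio"]
        return pd.DataFrame(columns=base)
    required = {"sample_id", "gene_id", "chrom", "pos", "ref_count", "alt_count"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing ASE columns {sorted(missing)}")
    for col in ("ref_count", "alt_count"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or not np.allclose(vals, np.round(vals)):
            raise ParseError(f"{path}: non-integer values in {col}")
        df[col] = vals.astype(np.int64)
    if (df["ref_count"] < 0).any() or (df["alt_count"] < 0).any():
        raise ParseError(f"{path}: negative allele counts")
    if "transcript_id" not in df.columns:
        df["transcript_id"] = pd.NA
    df["total"] = df["ref_count"] + df["alt_count"]
    with np.errstate(invalid="ignore"):
        df["allelic_ratio"] = np.where(
            df["total"] > 0,
            np.minimum(df["ref_count"], df["alt_count"]) / df["total"].replace(0, 1),
            np.nan,
        )
    return df


def write_ase_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in ASE_COLUMNS + ["cell_type"] if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols)


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gene_annotation(path, dialect: str) -> dict[str, GeneAnnotation]:
    """Read gene/transcript structures and compute strand-aware TSSs.

    Dialects: ``BED12`` (name = gene_id|transcript_id or plain id),
    ``gtf_lite`` (transcript rows with gene_id/transcript_id attributes),
    ``tss_table`` (gene_id, chrom, tss, strand — one synthetic 1-bp-anchored
    transcript per gene).
    """
    genes: dict[str, GeneAnnotation] = {}

    def add(gene_id: str, gene_name: str, tid: str, iv: GenomicInterval) -> None:
        if iv.strand not in {"+", "-"}:
            raise ValueError(f"transcript {tid}: strand must be + or -")
        gene = genes.setdefault(gene_id, GeneAnnotation(gene_id, gene_name, []))
        gene.transcripts.append(Transcript(tid, iv))

    if dialect == "BED12":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                parts = line.split("\t")
                if len(parts) < 6:
                    raise ParseError(f"{path}:{lineno}: BED needs >= 6 fields")
                chrom, start, end, name, _score, strand = parts[:6]
                if "|" in name:
                    gene_id, tid = name.split("|", 1)
                else:
                    gene_id, tid = name, name + ".t1"
                add(gene_id, gene_id, tid, GenomicInterval(chrom, int(start), int(end), strand))
    elif dialect == "gtf_lite":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise ParseError(f"{path}:{lineno}: GTF needs 9 fields")
                chrom, _src, feature, start1, end1, _score, strand, _frame, attrs = parts
                if feature != "transcript":
                    continue
                a = dict(_GTF_ATTR.findall(attrs))
                if "gene_id" not in a or "transcript_id" not in a:
                    raise ParseError(f"{path}:{lineno}: missing gene_id/transcript_id")
                add(
                    a["gene_id"],
                    a.get("gene_name", a["gene_id"]),
                    a["transcript_id"],
                    GenomicInterval(chrom, int(start1) - 1, int(end1), strand),
                )
    elif dialect == "tss_table":
        df = pd.read_csv(path, sep="\t")
        required = {"gene_id", "chrom", "tss", "strand"}
        if missing := required - set(df.columns):
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        for row in df.itertuples(index=False):
            # synthetic 1-bp transcript anchored so its strand-aware TSS
            # equals the stated position
            if row.strand == "+":
                iv = GenomicInterval(row.chrom, int(row.tss), int(row.tss) + 1, "+")
            elif row.strand == "-":
                iv = GenomicInterval(row.chrom, int(row.tss), int(row.tss) + 1, "-")
            else:
                raise ValueError(f"gene {row.gene_id}: strand must be + or -")
            add(row.gene_id, getattr(row, "gene_name", row.gene_id), f"{row.gene_id}.t1", iv)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    return genes


def default_registry() -> list[KnownDmr]:
    """The bundled registry of well-characterised human imprinted DMRs (GRCh38).

    Coordinates are approximate region anchors intended for QC scoring;
    supply your own BED6+2 for exact work.
    """
    from importlib.resources import files

    return read_dmr_registry(files("imprintscan.data") / "known_dmrs_hg38.bed")


def read_dmr_registry(path) -> list[KnownDmr]:
    """Read a known-imprinted-DMR registry as BED6+2 (name, ., strand, origin, notes)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise ParseError(f"{path}:{lineno}: registry BED needs >= 7 fields")
            chrom, start, end, name, _score, strand, origin = parts[:7]
            notes = parts[7] if len(parts) > 7 else ""
            out.append(
                KnownDmr(
                    name=name,
                    interval=GenomicInterval(chrom, int(start), int(end), strand),
                    germline_origin=origin,
                    notes=notes,
                )
            )
    return out


CANDIDATE_COLUMNS = [
    "gene_id",
    "chrom",
    "tss",
    "tier",
    "anchor_gene",
    "distance_bp",
    "has_promoter_dmr",
    "dmr_direction",
    "dmr_delta_pp",
    "dmr_q",
    "has_imprinted_expression_ESC",
    "has_imprinted_expression_NPC",
    "expression_class_ESC",
    "expression_class_NPC",
    "concordant",
    "ase_support",
    "isoform_specific",
    "near_gdmr",
]


def write_candidate_table(candidates: pd.DataFrame, path) -> None:
    """Write the final evidence-tiered candidate table (stable column order)."""
    out = candidates.copy()
    for col in CANDIDATE_COLUMNS:
        if col not in out.columns:
            out[col] = ""
    out = out[CANDIDATE_COLUMNS]
    out.to_csv(path, sep="\t", index=False)


def read_candidate_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_manifest(path) -> SampleManifest:
    """Read a sample manifest from YAML or TSV."""
    path = Path(path)
    if path.suffix in {".yml", ".yaml"}:
        with open(path) as fh:
            data = yaml.safe_load(fh)
        entries = data["samples"] if "samples" in data else data
    else:
        df = pd.read_csv(path, sep="\t")
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in manifest")
        entries = {
            row["sample_id"]: {k: v for k, v in row.items() if k != "sample_id" and pd.notna(v)}
            for _, row in df.iterrows()
        }
    return SampleManifest(entries=entries)
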