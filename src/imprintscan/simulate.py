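"""Seeded synthetic-data generator for the whole pipeline.

Emulates the statistical structure of uniparental stem-cell imprinting
data at desk scale:

* RRBS-like methylomes — CpGs concentrated in promoter windows, bimodal
  background levels (two beta components), beta noise per sample, and
  binomial read sampling at negative-binomial depth.  Planted
  parent-of-origin promoter DMRs put androgenetic (AG) and
  parthenogenetic (PG) samples on opposite sides of 50%; biparental
  samples sit midway (an allele mixture).  NPC samples share the imprint
  truth of their ESC counterparts.
* Negative-binomial gene counts with planted maternally/paternally
  expressed genes (MEG: PG mean = fold x AG mean; PEG mirrored;
  biparental = parental average).
* Binomial SNP allele counts with planted monoallelic loci (minor-allele
  leakage ~5%) and isoform-specific genes (one monoallelic and one
  biallelic transcript in the same cell type).
* Sperm/oocyte methylomes covering a handful of 1-kb windows (RRBS
  covers only a small CpG-dense fraction of any locus), with planted
  germline DMRs; persistent ones propagate concordantly into the
  uniparental ESC methylomes.

Every generator is a pure function of (scenario, seed): the same inputs
give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import GeneAnnotation, GenomicInterval, KnownDmr, MethylomeSample, Transcript


@dataclass
class SimulationScenario:
    """Study-condition knobs for the generator; defaults are the desk-scale run."""

    chrom: str = "chr19S"
    n_genes: int = 80
    first_tss: int = 100_000
    gene_spacing_bp: int = 25_000
    cpgs_per_promoter: int = 12
    promoter_flank_bp: int = 500

    # sample layout: 4 per uniparental group per stage (two replicates of
    # two lines), 2 biparental
    n_ag: int = 4
    n_pg: int = 4
    n_bi: int = 2
    stages: tuple[str, ...] = ("ESC", "NPC")

    # coverage: NB depth, mean 30x
    depth_mean: float = 30.0
    depth_dispersion: float = 8.0

    # background methylation: mixture of a low and a high beta component
    bg_low_mean: float = 0.08
    bg_high_mean: float = 0.88
    bg_weight_low: float = 0.7
    bg_concentration: float = 15.0
    sample_concentration: float = 80.0  # per-sample beta noise around the true level

    # planted promoter DMRs
    paternal_dmr_genes: tuple[int, ...] = (5, 15, 25, 35, 45)
    maternal_dmr_genes: tuple[int, ...] = ()
    dmr_delta_pp: float = 60.0

    # planted expression effects
    meg_genes: tuple[int, ...] = (5, 15, 25, 35, 45)
    peg_genes: tuple[int, ...] = ()
    fold_change: float = 4.0
    base_mean: float = 100.0
    nb_dispersion: float = 0.1
    gene_length_bp: int = 2000

    # cluster geometry: neighbors planted with relaxed evidence near anchors
    neighbor_expression_genes: tuple[int, ...] = (6, 16)  # imprinted-like expression only
    neighbor_dmr_genes: tuple[int, ...] = (26,)  # promoter DMR only, flat expression
    # a gene with a DMR but flat expression, far from any anchor
    dmr_only_flat_gene: int | None = 75

    # ASE
    ase_genes: tuple[int, ...] = (5, 15, 25, 35, 45)
    isoform_specific_genes: tuple[int, ...] = (15,)
    ase_snps_per_gene: int = 4
    ase_depth_mean: float = 40.0
    ase_leakage: float = 0.05

    # known-DMR registry for QC (intergenic; placed beyond the gene array
    # unless an explicit start is given)
    n_known_dmrs: int = 8
    known_dmr_start: int | None = None
    known_dmr_spacing: int = 10_000
    known_dmr_cpgs: int = 6

    # germline scan: gamete samples and covered 1-kb windows
    n_sperm: int = 4
    n_oocyte: int = 3
    germ_anchor_genes: tuple[int, ...] = (5, 45)
    germ_flank_bp: int = 200_000
    # absolute starts (bp) of gamete-covered 1-kb windows; placed mid-gap so
    # they never intersect a promoter window
    germ_covered_starts: tuple[int, ...] = (36_000, 136_000, 536_000, 736_000, 936_000)
    # planted gDMRs among the covered windows: (start, direction, persistent)
    germ_planted: tuple[tuple[int, str, bool], ...] = (
        (36_000, "oocyte_methylated", True),
        (536_000, "oocyte_methylated", True),
        (936_000, "sperm_methylated", False),
    )
    germ_cpgs_per_window: int = 8

    def __post_init__(self) -> None:
        for lst in (self.paternal_dmr_genes, self.maternal_dmr_genes, self.meg_genes,
                    self.peg_genes, self.ase_genes):
            bad = [i for i in lst if not 0 <= i < self.n_genes]
            if bad:
                raise ValueError(f"planted gene index out of range: {bad}")
        if set(self.paternal_dmr_genes) & set(self.maternal_dmr_genes):
            raise ValueError("a gene cannot carry both DMR directions")
        if set(self.meg_genes) & set(self.peg_genes):
            raise ValueError("a gene cannot be both MEG and PEG")
        if not 0 <= self.dmr_delta_pp <= 100:
            raise ValueError("dmr_delta_pp must lie in [0, 100]")


def dmr_benchmark_scenario(n_genes: int = 2000, n_dmrs: int = 20) -> SimulationScenario:
    """Promoter-DMR recovery benchmark: 2000 promoters, 20 paternal DMRs at 60pp."""
    step = n_genes // n_dmrs
    planted = tuple(range(step // 2, n_genes, step))[:n_dmrs]
    return SimulationScenario(
        n_genes=n_genes,
        gene_spacing_bp=5_000,
        paternal_dmr_genes=planted,
        meg_genes=(),
        neighbor_expression_genes=(),
        neighbor_dmr_genes=(),
        dmr_only_flat_gene=None,
        ase_genes=(),
        isoform_specific_genes=(),
        stages=("ESC",),
        n_bi=0,
    )


def expression_benchmark_scenario(n_genes: int = 500, n_each: int = 20) -> SimulationScenario:
    """Expression recovery benchmark: planted 4-fold MEGs and PEGs, mu=100, phi=0.1."""
    megs = tuple(range(0, 2 * n_each, 2))
    pegs = tuple(range(1, 2 * n_each, 2))
    return SimulationScenario(
        n_genes=n_genes,
        paternal_dmr_genes=(),
        meg_genes=megs,
        peg_genes=pegs,
        neighbor_expression_genes=(),
        neighbor_dmr_genes=(),
        dmr_only_flat_gene=None,
        ase_genes=(),
        isoform_specific_genes=(),
        stages=("ESC",),
        n_bi=0,
    )


# ---------------------------------------------------------------------------
# annotation & ground truth


def simulate_annotation(scenario: SimulationScenario) -> dict[str, GeneAnnotation]:
    """Evenly spaced genes on one chromosome, alternating strand."""
    genes: dict[str, GeneAnnotation] = {}
    for i in range(scenario.n_genes):
        gid = f"G{i:04d}"
        tss = scenario.first_tss + i * scenario.gene_spacing_bp
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            iv = GenomicInterval(scenario.chrom, tss, tss + scenario.gene_length_bp, "+")
        else:
            iv = GenomicInterval(scenario.chrom, tss - scenario.gene_length_bp + 1, tss + 1, "-")
        transcripts = [Transcript(f"{gid}.t1", iv)]
        if i in scenario.isoform_specific_genes:
            transcripts.append(Transcript(f"{gid}.t2", iv))
        genes[gid] = GeneAnnotation(gid, gid, transcripts)
    return genes


def gene_lengths(scenario: SimulationScenario) -> pd.Series:
    ids = [f"G{i:04d}" for i in range(scenario.n_genes)]
    return pd.Series(scenario.gene_length_bp, index=ids, dtype=float)


def ground_truth(scenario: SimulationScenario) -> pd.DataFrame:
    """Per-gene ledger of every planted property, including expected tiers."""
    rows = []
    anchors = sorted(set(scenario.paternal_dmr_genes) & set(scenario.meg_genes)
                     | set(scenario.maternal_dmr_genes) & set(scenario.peg_genes))
    radius = 500_000
    for i in range(scenario.n_genes):
        tss = scenario.first_tss + i * scenario.gene_spacing_bp
        is_pat = i in scenario.paternal_dmr_genes or i in scenario.neighbor_dmr_genes or i == scenario.dmr_only_flat_gene
        is_mat = i in scenario.maternal_dmr_genes
        is_meg = i in scenario.meg_genes or i in scenario.neighbor_expression_genes
        is_peg = i in scenario.peg_genes
        tier = ""
        anchor = ""
        if i in anchors:
            tier = "1_stringent"
        else:
            near = [
                a for a in anchors
                if abs((scenario.first_tss + a * scenario.gene_spacing_bp) - tss) <= radius
            ]
            if near and (is_pat or is_mat or is_meg or is_peg):
                tier = "2_cluster"
                anchor = f"G{min(near, key=lambda a: abs(a - i)):04d}"
        rows.append(
            {
                "gene_id": f"G{i:04d}",
                "tss": tss,
                "is_paternal_dmr": is_pat,
                "is_maternal_dmr": is_mat,
                "dmr_delta_pp": scenario.dmr_delta_pp if (is_pat or is_mat) else 0.0,
                "is_meg": is_meg,
                "is_peg": is_peg,
                "fold_change": scenario.fold_change if (is_meg or is_peg) else 1.0,
                "is_monoallelic": i in scenario.ase_genes,
                "is_isoform_specific": i in scenario.isoform_specific_genes,
                "true_tier": tier,
                "anchor": anchor,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# methylomes


def _beta(rng: np.random.Generator, mean: np.ndarray, conc: float) -> np.ndarray:
    m = np.clip(mean, 0.01, 0.99)
    return rng.beta(m * conc, (1 - m) * conc)


def _sample_layout(scenario: SimulationScenario) -> list[tuple[str, str, str]]:
    """(sample_id, origin, stage) for every somatic sample."""
    out = []
    for stage in scenario.stages:
        for origin, n in [
            ("androgenetic", scenario.n_ag),
            ("parthenogenetic", scenario.n_pg),
            ("biparental", scenario.n_bi),
        ]:
            for k in range(n):
                out.append((f"{origin[:2].upper()}_{stage}_{k + 1}", origin, stage))
    return out


def _promoter_cpg_positions(scenario: SimulationScenario) -> tuple[np.ndarray, np.ndarray]:
    """(positions, gene_index) for CpGs tiled across every promoter window."""
    flank = scenario.promoter_flank_bp
    n_cpg = scenario.cpgs_per_promoter
    offsets = np.linspace(-flank, flank - 1, n_cpg).astype(int)
    pos, gidx = [], []
    for i in range(scenario.n_genes):
        tss = scenario.first_tss + i * scenario.gene_spacing_bp
        pos.append(tss + offsets)
        gidx.append(np.full(n_cpg, i))
    return np.concatenate(pos), np.concatenate(gidx)


def _known_dmr_regions(scenario: SimulationScenario) -> list[KnownDmr]:
    base = scenario.known_dmr_start
    if base is None:
        base = scenario.first_tss + scenario.n_genes * scenario.gene_spacing_bp + 1_000_000
    out = []
    for j in range(scenario.n_known_dmrs):
        start = base + j * scenario.known_dmr_spacing
        origin = "paternal" if j % 2 == 0 else "maternal"
        out.append(
            KnownDmr(
                name=f"KNOWN_DMR_{j}",
                interval=GenomicInterval(scenario.chrom, start, start + 500),
                germline_origin=origin,
            )
        )
    return out


def synthetic_registry(scenario: SimulationScenario) -> list[KnownDmr]:
    """The known-imprinted-DMR registry matching the simulated genome."""
    return _known_dmr_regions(scenario)


def simulate_methylomes(
    scenario: SimulationScenario,
    seed: int,
) -> tuple[list[MethylomeSample], pd.DataFrame]:
    """Somatic (AG/PG/BI, ESC/NPC) methylomes plus the ground-truth ledger."""
    rng = np.random.default_rng(seed)
    pos, gidx = _promoter_cpg_positions(scenario)
    n_cpg = pos.size

    # true background level per CpG, shared across all samples (null genes)
    low = rng.random(n_cpg) < scenario.bg_weight_low
    bg_mean = np.where(low, scenario.bg_low_mean, scenario.bg_high_mean)
    bg_level = _beta(rng, bg_mean, scenario.bg_concentration)

    d = scenario.dmr_delta_pp / 200.0  # half-delta as a fraction
    pat = np.isin(gidx, np.array(scenario.paternal_dmr_genes
                                 + scenario.neighbor_dmr_genes
                                 + ((scenario.dmr_only_flat_gene,)
                                    if scenario.dmr_only_flat_gene is not None else ())))
    mat = np.isin(gidx, np.array(scenario.maternal_dmr_genes, dtype=int))

    # germline-DMR propagation into uniparental ESC/NPC methylomes
    germ_pos, germ_level_ag, germ_level_pg = _germ_propagated_levels(scenario)

    # QC registry CpGs
    qc_pos, qc_origin_is_pat = _registry_cpgs(scenario)

    def true_level(origin: str) -> np.ndarray:
        level = bg_level.copy()
        if origin == "androgenetic":
            level[pat] = 0.5 + d
            level[mat] = 0.5 - d
        elif origin == "parthenogenetic":
            level[pat] = 0.5 - d
            level[mat] = 0.5 + d
        else:  # biparental: allele mixture
            level[pat] = 0.5
            level[mat] = 0.5
        return level

    samples = []
    for sample_id, origin, stage in _sample_layout(scenario):
        lvl = true_level(origin)
        lvl = _beta(rng, lvl, scenario.sample_concentration)
        depth = rng.negative_binomial(
            scenario.depth_dispersion,
            scenario.depth_dispersion / (scenario.depth_dispersion + scenario.depth_mean),
            n_cpg,
        )
        meth = rng.binomial(depth, lvl)

        all_pos = [pos]
        all_meth = [meth]
        all_depth = [depth]

        # propagated germline windows (uniparental only)
        if germ_pos.size and origin in ("androgenetic", "parthenogenetic"):
            g_lvl = germ_level_ag if origin == "androgenetic" else germ_level_pg
            g_lvl = _beta(rng, g_lvl, scenario.sample_concentration)
            g_depth = rng.negative_binomial(
                scenario.depth_dispersion,
                scenario.depth_dispersion / (scenario.depth_dispersion + scenario.depth_mean),
                germ_pos.size,
            )
            all_pos.append(germ_pos)
            all_meth.append(rng.binomial(g_depth, g_lvl))
            all_depth.append(g_depth)

        # known-DMR registry CpGs: ~50% in biparental, allele-specific in
        # uniparental genomes
        if qc_pos.size:
            if origin == "biparental":
                q_lvl = np.full(qc_pos.size, 0.5)
            elif origin == "androgenetic":
                q_lvl = np.where(qc_origin_is_pat, 0.95, 0.05)
            else:
                q_lvl = np.where(qc_origin_is_pat, 0.05, 0.95)
            q_lvl = _beta(rng, q_lvl, scenario.sample_concentration)
            q_depth = rng.negative_binomial(
                scenario.depth_dispersion,
                scenario.depth_dispersion / (scenario.depth_dispersion + scenario.depth_mean),
                qc_pos.size,
            )
            all_pos.append(qc_pos)
            all_meth.append(rng.binomial(q_depth, q_lvl))
            all_depth.append(q_depth)

        p = np.concatenate(all_pos)
        m = np.concatenate(all_meth)
        t = np.concatenate(all_depth)
        calls = pd.DataFrame(
            {"chrom": scenario.chrom, "pos": p, "meth": m, "unmeth": t - m}
        ).sort_values("pos", kind="stable").reset_index(drop=True)
        samples.append(MethylomeSample(sample_id, origin, stage, calls, dyads_merged=True))
    return samples, ground_truth(scenario)


def _registry_cpgs(scenario: SimulationScenario) -> tuple[np.ndarray, np.ndarray]:
    pos, is_pat = [], []
    for dmr in _known_dmr_regions(scenario):
        p = np.arange(dmr.interval.start + 10, dmr.interval.start + 10 + 50 * scenario.known_dmr_cpgs, 50)
        pos.append(p)
        is_pat.append(np.full(p.size, dmr.germline_origin == "paternal"))
    if not pos:
        return np.empty(0, dtype=int), np.empty(0, dtype=bool)
    return np.concatenate(pos), np.concatenate(is_pat)


# ---------------------------------------------------------------------------
# germline methylomes


def scan_region_span(scenario: SimulationScenario) -> GenomicInterval:
    """The gamete scan region implied by the scenario's anchor genes."""
    anchor_tss = [
        scenario.first_tss + i * scenario.gene_spacing_bp for i in scenario.germ_anchor_genes
    ]
    start = max(0, min(anchor_tss) - scenario.gene_length_bp - scenario.germ_flank_bp)
    end = max(anchor_tss) + scenario.gene_length_bp + scenario.germ_flank_bp
    return GenomicInterval(scenario.chrom, start, end)


def _germ_window_positions(scenario: SimulationScenario) -> dict[int, np.ndarray]:
    """window start -> CpG positions for each gamete-covered 1-kb window."""
    out = {}
    for start in scenario.germ_covered_starts:
        step = 1000 // scenario.germ_cpgs_per_window
        out[start] = np.arange(start + step // 2, start + 1000, step)[: scenario.germ_cpgs_per_window]
    return out


def _germ_propagated_levels(
    scenario: SimulationScenario,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CpG positions and true AG/PG levels for persistent germline DMRs."""
    windows = _germ_window_positions(scenario)
    pos, ag, pg = [], [], []
    for off, direction, persistent in scenario.germ_planted:
        if not persistent:
            continue
        p = windows[off]
        pos.append(p)
        if direction == "oocyte_methylated":  # maternal methylation -> PG high
            ag.append(np.full(p.size, 0.1))
            pg.append(np.full(p.size, 0.9))
        else:
            ag.append(np.full(p.size, 0.9))
            pg.append(np.full(p.size, 0.1))
    if not pos:
        e = np.empty(0)
        return np.empty(0, dtype=int), e, e
    return np.concatenate(pos), np.concatenate(ag), np.concatenate(pg)


def simulate_germ(
    scenario: SimulationScenario,
    seed: int,
) -> tuple[list[MethylomeSample], pd.DataFrame]:
    """Sperm and oocyte methylomes over the covered scan windows, plus window truth."""
    rng = np.random.default_rng(seed + 104729)  # distinct stream from somatic draws
    windows = _germ_window_positions(scenario)
    planted = {start: (direction, persistent) for start, direction, persistent in scenario.germ_planted}

    truth_rows = []
    pos_all, sperm_mean, oocyte_mean = [], [], []
    region = scan_region_span(scenario)
    for start, p in windows.items():
        if not (region.start <= start and start + 1000 <= region.end):
            raise ValueError(f"covered window at {start} lies outside the scan region")
        if start in planted:
            direction, persistent = planted[start]
            s_lvl, o_lvl = (0.9, 0.1) if direction == "sperm_methylated" else (0.1, 0.9)
        else:
            direction, persistent = "none", False
            s_lvl = o_lvl = 0.5  # covered null windows: equal in both gametes
        pos_all.append(p)
        sperm_mean.append(np.full(p.size, s_lvl))
        oocyte_mean.append(np.full(p.size, o_lvl))
        truth_rows.append(
            {
                "window_start": start,
                "window_end": start + 1000,
                "direction": direction,
                "persistent": persistent,
                "covered": True,
            }
        )
    pos_arr = np.concatenate(pos_all)
    s_mean = np.concatenate(sperm_mean)
    o_mean = np.concatenate(oocyte_mean)

    samples = []
    for origin, n, mean in [("sperm", scenario.n_sperm, s_mean), ("oocyte", scenario.n_oocyte, o_mean)]:
        for k in range(n):
            lvl = _beta(rng, mean, scenario.sample_concentration)
            depth = rng.negative_binomial(
                scenario.depth_dispersion,
                scenario.depth_dispersion / (scenario.depth_dispersion + scenario.depth_mean),
                pos_arr.size,
            )
            meth = rng.binomial(depth, lvl)
            calls = pd.DataFrame(
                {"chrom": scenario.chrom, "pos": pos_arr, "meth": meth, "unmeth": depth - meth}
            ).sort_values("pos", kind="stable").reset_index(drop=True)
            samples.append(MethylomeSample(f"{origin}_{k + 1}", origin, "germ", calls))
    return samples, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# counts


def simulate_counts(
    scenario: SimulationScenario,
    seed: int,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """stage -> genes x samples NB count matrix, plus the ground-truth ledger."""
    rng = np.random.default_rng(seed + 15485863)
    truth = ground_truth(scenario)
    n = scenario.n_genes
    ids = [f"G{i:04d}" for i in range(n)]

    # gene base means: planted genes at the stated base mean, null genes
    # lognormal around it
    base = np.exp(rng.normal(np.log(scenario.base_mean), 0.7, n))
    megs = np.array([i in scenario.meg_genes or i in scenario.neighbor_expression_genes for i in range(n)])
    pegs = np.array([i in scenario.peg_genes for i in range(n)])
    base[megs | pegs] = scenario.base_mean

    ag_mean = np.where(megs, base, np.where(pegs, base * scenario.fold_change, base))
    pg_mean = np.where(megs, base * scenario.fold_change, np.where(pegs, base, base))
    bi_mean = 0.5 * (ag_mean + pg_mean)

    phi = scenario.nb_dispersion
    matrices: dict[str, pd.DataFrame] = {}
    for stage in scenario.stages:
        cols = {}
        for sample_id, origin, s_stage in _sample_layout(scenario):
            if s_stage != stage:
                continue
            mu = {"androgenetic": ag_mean, "parthenogenetic": pg_mean, "biparental": bi_mean}[origin]
            cols[sample_id] = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu))
        matrices[stage] = pd.DataFrame(cols, index=ids)
    return matrices, truth


# ---------------------------------------------------------------------------
# ASE


def simulate_ase(
    scenario: SimulationScenario,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Public-panel-style per-SNP allele counts, plus the ground-truth ledger."""
    rng = np.random.default_rng(seed + 32452843)
    truth = ground_truth(scenario)
    rows = []
    cell_types = ["pluripotent", "neuronal", "MSC"]
    for i in range(scenario.n_genes):
        gid = f"G{i:04d}"
        mono = i in scenario.ase_genes
        iso = i in scenario.isoform_specific_genes
        if not mono and not iso:
            continue
        tss = scenario.first_tss + i * scenario.gene_spacing_bp
        for k in range(scenario.ase_snps_per_gene):
            ct = cell_types[k % len(cell_types)]
            total = max(1, int(rng.negative_binomial(
                scenario.depth_dispersion,
                scenario.depth_dispersion / (scenario.depth_dispersion + scenario.ase_depth_mean),
            )))
            transcripts = [f"{gid}.t1", f"{gid}.t2"] if iso else [f"{gid}.t1"]
            for tid in transcripts:
                biallelic_isoform = iso and tid.endswith(".t2")
                p_minor = 0.5 if biallelic_isoform or not mono else scenario.ase_leakage
                minor = rng.binomial(total, p_minor)
                if rng.random() < 0.5:
                    ref, alt = total - minor, minor
                else:
                    ref, alt = minor, total - minor
                rows.append(
                    {
                        "sample_id": f"public_{ct}_{k + 1}",
                        "gene_id": gid,
                        "transcript_id": tid,
                        "chrom": scenario.chrom,
                        "pos": tss + 100 + 37 * k,
                        "ref_count": ref,
                        "alt_count": alt,
                        "cell_type": ct,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "gene_id", "transcript_id", "chrom", "pos",
                 "ref_count", "alt_count", "cell_type"],
    )
    if len(df):
        df["total"] = df["ref_count"] + df["alt_count"]
        df["allelic_ratio"] = np.minimum(df["ref_count"], df["alt_count"]) / df["total"]
    return df, truth
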