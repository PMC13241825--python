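# imprintscan

Discovery of putative imprinted genes from uniparental stem-cell
methylomes and transcriptomes.

Genomic imprinting is parent-of-origin-dependent monoallelic
expression, established by germline differentially methylated regions
(gDMRs) laid down in sperm and oocyte and reinforced by secondary DMRs
after implantation. Androgenetic (all-paternal, AG) and
parthenogenetic (all-maternal, PG) human embryonic stem cells separate
the two parental epigenomes into different dishes: a paternally
methylated promoter is near-fully methylated in AG cells and unmethylated
in PG cells, and a maternally expressed gene (MEG) is expressed in PG
and silent in AG. This package implements the resulting discovery
pipeline for researchers with RRBS methylation calls and RNA-seq counts
from such lines:

1. **qc** — score every sample at a registry of known imprinted DMRs;
   a biparental sample is kept only if at least half of the assessable
   DMRs show normal (30–70%) methylation, and the aberration report
   groups eroded DMRs into retained-difference vs uniform-hyper.
2. **promoter-dmr** — test each expressed gene's promoter
   (TSS ± 500 bp) between AG and PG by Mann–Whitney on pooled per-CpG
   levels; call DMRs at Benjamini–Hochberg q ≤ 0.05 and |ΔAG−PG| ≥ 25
   percentage points, with parental direction from the sign of Δ.
3. **expression** — TMM-normalised counts, TPM > 1 expressed filter, a
   negative-binomial exact test of PG vs AG per stage; genes at q ≤
   0.05 are MEG-like (up in PG) or PEG-like (up in AG).
4. **ase** — allelic ratio min(ref, alt)/total at heterozygous SNPs:
   < 0.15 monoallelic, 0.15–0.3 partially monoallelic, > 5 reads
   required (≥ 20 in stringent mode); isoform-specific imprinting
   flagged when one transcript is monoallelic and another biallelic in
   the same cell type.
5. **gdmr-scan** — 1-kb windows across an anchor locus ± 200 kb, exact
   permutation test of sperm vs oocyte methylation with BH control over
   the tested universe; calls are checked for concordant persistence in
   the uniparental ESCs, separating germline candidates from secondary
   DMRs.
6. **integrate** — tier 1 = promoter DMR + imprinted-like expression +
   concordance (paternal DMR ↔ MEG-like, maternal ↔ PEG-like); tier 2 =
   relaxed criteria (DMR *or* imprinted-like expression) within 500 kb
   of a tier-1 anchor, reflecting the clustering of imprinted genes.
   ASE and gDMR proximity are annotated, never required.

A seeded synthetic-data generator (`imprintscan simulate`) produces
methylomes, counts, ASE tables, gamete methylomes, annotation and a
ground-truth ledger with the statistical structure the analysis
assumes, so the whole pipeline runs and is validated without any
external data. See `docs/methods.md` for models, defaults and
limitations.

## Worked example

```sh
imprintscan simulate --seed 11 --out demo
imprintscan run-all --manifest demo/manifest.yaml --out demo_out --seed 11
# 9 candidate(s) (5 tier-1) -> demo_out/candidates.tsv
```

`demo_out/candidates.tsv` (columns abridged):

```
gene_id   tss      tier         anchor  dmr_direction  dmr_delta_pp  expr_ESC            ase_support
G0005      225000  1_stringent          paternal       62.8          MEG_like            monoallelic
G0006      250000  2_cluster    G0005                                MEG_like            none
G0015      475000  1_stringent          paternal       60.0          MEG_like            monoallelic
G0016      500000  2_cluster    G0015                                MEG_like            none
G0024      700000  2_cluster    G0025                                not_imprinted_like  none
G0025      725000  1_stringent          paternal       60.4          MEG_like            monoallelic
G0026      750000  2_cluster    G0025   paternal       61.5          not_imprinted_like  none
G0035      975000  1_stringent          paternal       60.2          MEG_like            monoallelic
G0045     1225000  1_stringent          paternal       61.1          MEG_like            monoallelic
```

The five tier-1 genes carry a paternal (AG-hypermethylated) promoter
DMR of ~60 pp together with concordant MEG-like expression and
monoallelic ASE support — the full stringent evidence chain. G0006 and
G0016 are cluster candidates through expression alone, and G0026
through its DMR alone (its expression is flat — the signature a gene
with isoform-specific imprinting would leave). G0024 is a relaxed-tier
false positive from a single MEG-like call in NPCs; tier 2 trades
specificity for sensitivity by design, which is why tier membership is
reported rather than filtered. A gene with a DMR but flat expression
outside any cluster lands in `dmr_only.tsv` instead.

`demo_out/gdmr_calls.tsv` shows the germline scan at this locus:

```
start   germ_direction     delta_pp  q_value  persistent  origin_class
36000   oocyte_methylated  -79.6     0.048    True        germline_candidate
536000  oocyte_methylated  -77.3     0.048    True        germline_candidate
936000  sperm_methylated    79.6     0.048    False       germline_non_persistent
```

Two oocyte-methylated windows persist concordantly
(PG-hypermethylated) in the uniparental ESCs and are germline
candidates; the third is significant in gametes but does not persist.
With 4 sperm vs 3 oocyte samples each window's permutation p sits at
the enumeration floor 1/35 ≈ 0.029, so calls at FDR 0.05 are only
possible over a small tested universe — the universe size is always
reported with the calls.

Every stage is also importable directly
(`imprintscan.promoter.call_promoter_dmrs`,
`imprintscan.expression.nb_exact_test`, `imprintscan.ase.classify_ase`,
…), and `run_all` accepts in-memory inputs.

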