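"""Expression normalisation and parent-of-origin expression classification.

Raw gene counts are normalised with TMM (trimmed mean of M-values) scaling
factors and converted to CPM/TPM.  The expressed universe for a stage is
genes exceeding a TPM threshold in at least two samples of that stage.
Differential expression between parthenogenetic (PG) and androgenetic (AG)
groups uses a two-sided negative-binomial exact test on library-equalised
group sums, with a per-gene dispersion floored at the common estimate.
Genes with BH q <= alpha are classed MEG-like (up in PG, i.e. maternally
expressed) or PEG-like (up in AG) by the sign of log2(PG/AG).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_qvalues
from .config import PipelineConfig

log = logging.getLogger(__name__)

EXPRESSION_CLASSES = ("MEG_like", "PEG_like", "not_imprinted_like", "not_expressed")


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: count / library size * 1e6, per sample."""
    lib = counts.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return counts / lib * 1e6


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-normalised rates rescaled to 1e6 per sample."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    if (denom <= 0).any():
        raise ValueError("zero length-normalised library")
    return rate / denom * 1e6


def tmm_factors(
    counts: pd.DataFrame,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """TMM scaling factors, rescaled to geometric mean 1.

    The reference defaults to the sample whose upper-quartile count rate
    is closest to the mean upper quartile.  For each sample, M-values
    (log2 ratio vs reference, depth-corrected) are doubly trimmed — 30%
    of the M ranks and 5% of the A ranks from each tail — and averaged
    with delta-method precision weights.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs >= 2 samples")
    lib = counts.sum(axis=0).astype(float)
    if ref_sample is None:
        uq = counts.apply(lambda col: np.quantile(col / col.sum(), 0.75))
        ref_sample = (uq - uq.mean()).abs().idxmin()
    yr = counts[ref_sample].to_numpy(dtype=float)
    nr = lib[ref_sample]

    factors = {}
    for s in counts.columns:
        ys = counts[s].to_numpy(dtype=float)
        ns = lib[s]
        ok = (ys > 0) & (yr > 0)
        if ok.sum() < 2:
            log.warning("TMM: sample %s shares too few expressed genes with reference; factor 1", s)
            factors[s] = 1.0
            continue
        ps, pr = ys[ok] / ns, yr[ok] / nr
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        if np.max(np.abs(m)) < 1e-6:  # identical compositions
            factors[s] = 1.0
            continue
        v = (ns - ys[ok]) / (ns * ys[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        # rank-based double trim
        n = m.size
        lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            factors[s] = 1.0
            continue
        # inverse-variance weighted trimmed mean of M-values
        factors[s] = float(2 ** (np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])))
    f = pd.Series(factors).reindex(counts.columns)
    return f / np.exp(np.mean(np.log(f)))


@dataclass
class NormalizedExpression:
    counts: pd.DataFrame
    cpm: pd.DataFrame
    tpm: pd.DataFrame | None
    tmm: pd.Series


def normalize(counts: pd.DataFrame, lengths: pd.Series | None = None) -> NormalizedExpression:
    f = tmm_factors(counts)
    eff = counts.sum(axis=0) * f
    cpm_mat = counts / eff * 1e6
    tpm_mat = tpm(counts, lengths) if lengths is not None else None
    return NormalizedExpression(counts=counts, cpm=cpm_mat, tpm=tpm_mat, tmm=f)


def expressed_filter(
    norm: NormalizedExpression,
    stage_samples: list[str],
    config: PipelineConfig,
) -> set[str]:
    """Genes with TPM (CPM fallback) > threshold in >= 2 samples of the stage."""
    mat = norm.tpm if norm.tpm is not None else norm.cpm
    sub = mat[stage_samples]
    n_pass = (sub > config.expressed_tpm).sum(axis=1)
    return set(sub.index[n_pass >= 2])


def _equalized(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Counts rescaled to a common effective library size and rounded."""
    eff = counts.sum(axis=0) * factors
    target = float(np.exp(np.mean(np.log(eff))))
    return (counts / eff * target).round()


def _mom_dispersions(eq: pd.DataFrame, groups: list[list[str]]) -> np.ndarray:
    """Method-of-moments per-gene NB dispersion pooled within groups."""
    num = np.zeros(len(eq))
    den = np.zeros(len(eq))
    for cols in groups:
        sub = eq[cols].to_numpy(dtype=float)
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        ok = mu > 0
        num[ok] += var[ok] - mu[ok]
        den[ok] += mu[ok] ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(den > 0, num / den, 0.0)
    return np.clip(phi, 0.0, None)


def _exact_nb_p(sa: float, sb: float, na: int, nb_: int, phi: float) -> float:
    """Two-sided conditional exact NB test (double-tail) on group sums.

    Under H0 both groups share the per-sample mean mu = (sa+sb)/(na+nb).
    The group sums are NB with sizes na/phi and nb/phi; the p-value sums
    the probabilities of all splits of the total no more likely than the
    observed one.  phi -> 0 reduces to the binomial (Poisson) split.
    """
    t = int(round(sa + sb))
    if t == 0:
        return 1.0
    a_obs = int(round(sa))
    avals = np.arange(t + 1)
    if phi <= 1e-12:
        logp = stats.binom.logpmf(avals, t, na / (na + nb_))
    else:
        mu = (sa + sb) / (na + nb_)
        size_a, size_b = na / phi, nb_ / phi
        pa = size_a / (size_a + na * mu)
        pb = size_b / (size_b + nb_ * mu)
        logp = stats.nbinom.logpmf(avals, size_a, pa) + stats.nbinom.logpmf(t - avals, size_b, pb)
    p = np.exp(logp - logp.max())
    p /= p.sum()
    return float(min(1.0, p[p <= p[a_obs] * (1 + 1e-10)].sum()))


def nb_exact_test(
    counts: pd.DataFrame,
    ag_samples: list[str],
    pg_samples: list[str],
    dispersion_mode: str = "auto",
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Per-gene two-sided NB exact test of PG vs AG.

    Returns a DataFrame indexed by gene with ``log2fc_pg_over_ag``,
    ``p_value`` and the dispersion used.  Dispersion per gene is
    max(common estimate, tagwise method-of-moments shrunk 50% toward
    common); ``dispersion_mode='poisson'`` forces zero dispersion.
    """
    if len(ag_samples) < 2 or len(pg_samples) < 2:
        raise ValueError("need >= 2 samples per group")
    sub = counts[ag_samples + pg_samples]
    f = tmm_factors(sub)
    eq = _equalized(sub, f)

    if dispersion_mode == "poisson":
        phi = np.zeros(len(eq))
    else:
        tagwise = _mom_dispersions(eq, [ag_samples, pg_samples])
        expressed = eq.mean(axis=1).to_numpy() > 1
        # common dispersion: mean of per-gene MoM estimates (the per-gene
        # MoM is ~unbiased, so the mean is too; the median biases low
        # because the sampling distribution is right-skewed)
        common = float(np.mean(tagwise[expressed])) if expressed.any() else 0.0
        shrunk = 0.5 * tagwise + 0.5 * common
        phi = np.maximum(common, shrunk)

    na, nb_ = len(ag_samples), len(pg_samples)
    sa = eq[ag_samples].sum(axis=1).to_numpy()
    sb = eq[pg_samples].sum(axis=1).to_numpy()
    pvals = np.ones(len(eq))
    for i in range(len(eq)):
        if sa[i] + sb[i] > 0:
            pvals[i] = _exact_nb_p(sa[i], sb[i], na, nb_, float(phi[i]))

    mean_ag = eq[ag_samples].mean(axis=1).to_numpy()
    mean_pg = eq[pg_samples].mean(axis=1).to_numpy()
    log2fc = np.log2((mean_pg + prior_count) / (mean_ag + prior_count))
    zero = (sa + sb) == 0
    log2fc[zero] = 0.0
    return pd.DataFrame(
        {"log2fc_pg_over_ag": log2fc, "p_value": pvals, "dispersion": phi},
        index=eq.index,
    )


def classify_imprinted_expression(
    tests: pd.DataFrame,
    expressed: set[str],
    config: PipelineConfig,
    stage: str = "ESC",
) -> pd.DataFrame:
    """Assign MEG_like / PEG_like / not_imprinted_like / not_expressed per gene.

    BH is applied within the expressed universe only; genes outside it are
    not_expressed regardless of their statistic.
    """
    out = tests.copy()
    out["stage"] = stage
    in_universe = out.index.isin(expressed)
    out["q_value"] = np.nan
    if in_universe.any():
        out.loc[in_universe, "q_value"] = bh_qvalues(out.loc[in_universe, "p_value"].to_numpy())
    cls = np.full(len(out), "not_expressed", dtype=object)
    sig = in_universe & (out["q_value"].to_numpy() <= config.dmr_alpha)
    fc = out["log2fc_pg_over_ag"].to_numpy()
    cls[in_universe] = "not_imprinted_like"
    cls[sig & (fc > 0)] = "MEG_like"
    cls[sig & (fc < 0)] = "PEG_like"
    out["class"] = cls
    return out


def classify_from_external(
    de_table: pd.DataFrame,
    expressed: set[str],
    config: PipelineConfig,
    stage: str = "ESC",
) -> pd.DataFrame:
    """Adapter: classify from an externally produced DE table.

    Expects columns ``gene_id``, ``log2fc_pg_over_ag``, ``p_value`` —
    e.g. exported from an edgeR GLM fit.
    """
    t = de_table.set_index("gene_id")[["log2fc_pg_over_ag", "p_value"]]
    return classify_imprinted_expression(t, expressed, config, stage=stage)
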