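"""Statistical primitives shared across pipeline stages."""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .model import GenomicInterval, MethylomeSample


def pooled_region_mean(
    sample: MethylomeSample,
    region: GenomicInterval,
    min_cov: int,
    min_cpgs: int,
) -> tuple[float | None, int, int]:
    """Pooled-count mean methylation in a region, in percent.

    Only CpGs with coverage >= ``min_cov`` are informative.  Returns
    ``(mean_percent | None, n_informative_cpgs, total_reads)``; the mean is
    None ("no data") when fewer than ``min_cpgs`` CpGs are informative.
    The pool is count-weighted: sum(meth) / sum(meth + unmeth).
    """
    meth_arr, unmeth_arr = sample.region_counts(region)
    total = meth_arr + unmeth_arr
    keep = total >= min_cov
    n = int(keep.sum())
    reads = int(total[keep].sum())
    if n < min_cpgs:
        return None, n, reads
    meth = int(meth_arr[keep].sum())
    return 100.0 * meth / reads, n, reads


def permutation_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    max_exact: int = 100_000,
    n_mc: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided permutation p for |mean(A) - mean(B)|.

    All C(nA+nB, nA) label assignments are enumerated when feasible
    (<= ``max_exact``); otherwise Monte-Carlo with an add-one correction.
    The observed assignment is always counted, so p >= 1/N.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    observed = abs(a.mean() - b.mean())
    total_sum = pooled.sum()
    n_assign = comb(n, na)
    # stat for an assignment is a function of the A-subset sum only
    if n_assign <= max_exact:
        count = 0
        for idx in combinations(range(n), na):
            sa = pooled[list(idx)].sum()
            stat = abs(sa / na - (total_sum - sa) / (n - na))
            if stat >= observed - 1e-12:
                count += 1
        return count / n_assign
    rng = rng if rng is not None else np.random.default_rng()
    count = 0
    for _ in range(n_mc):
        perm = rng.permutation(pooled)
        sa = perm[:na].sum()
        stat = abs(sa / na - (total_sum - sa) / (n - na))
        if stat >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_mc + 1)


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def make_default_config() -> PipelineConfig:
    return PipelineConfig()
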