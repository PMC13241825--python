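"""Promoter windows, rank tests against enumeration oracles, DMR calling."""

from itertools import combinations

import numpy as np
import pytest
from scipy.stats import rankdata

from imprintscan.config import PipelineConfig
from imprintscan.model import GeneAnnotation, GenomicInterval, Transcript
from imprintscan.promoter import call_promoter_dmrs, promoter_window, summarize_promoter
from imprintscan.promoter import test_promoter as promoter_rank_test
from conftest import make_sample


def exact_ranksum_p(a, b):
    """Two-sided exact Mann-Whitney p by full enumeration of group assignments.

    Under the null every split of the pooled values into groups of sizes
    |a|, |b| is equally likely; the U statistic's null distribution is
    symmetric, so the two-sided p is the probability of a U at least as
    far from its mean as observed.
    """
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    ranks = rankdata(pooled)
    center = na * (n - na) / 2 + na * (na + 1) / 2  # mean rank-sum of group A
    obs = abs(ranks[:na].sum() - center)
    count = total = 0
    for idx in combinations(range(n), na):
        total += 1
        if abs(ranks[list(idx)].sum() - center) >= obs - 1e-9:
            count += 1
    return count / total


def annotated_gene(gene_id="G1", chrom="chr1", start=9000, end=12000, strand="+"):
    return GeneAnnotation(
        gene_id, gene_id, [Transcript(f"{gene_id}.t1", GenomicInterval(chrom, start, end, strand))]
    )


class TestPromoterWindow:
    def test_plus_strand(self):
        g = annotated_gene(start=10000, end=12000, strand="+")
        w = promoter_window(g, flank_bp=500)
        assert (w.start, w.end) == (9500, 10500)

    def test_minus_strand_centered_on_right_end(self):
        g = annotated_gene(start=1000, end=2000, strand="-")
        w = promoter_window(g, flank_bp=500)
        # TSS is 1999 (0-based rightmost base)
        assert (w.start, w.end) == (1499, 2499)

    def test_clipped_at_chromosome_start(self):
        g = annotated_gene(start=200, end=2000, strand="+")
        w = promoter_window(g, flank_bp=500)
        assert (w.start, w.end) == (0, 700)

    def test_unknown_transcript(self):
        with pytest.raises(KeyError):
            promoter_window(annotated_gene(), transcript_id="nope")


class TestSummaries:
    def test_pooled_mean_and_counts(self, config):
        g = annotated_gene(start=10000, strand="+")
        w = promoter_window(g, flank_bp=500)
        s = make_sample([(9600, 0, 10), (9700, 10, 0), (9800, 5, 5)])
        summ = summarize_promoter(s, g, w, config)
        assert summ.mean_meth_percent == pytest.approx(50.0)
        assert summ.n_cpgs == 3 and summ.total_reads == 30

    def test_no_coverage_window(self, config):
        g = annotated_gene(start=10000)
        w = promoter_window(g, flank_bp=500)
        summ = summarize_promoter(g and make_sample([(5, 1, 1)]), g, w, config)
        assert summ.mean_meth_percent is None and summ.n_cpgs == 0

    def test_low_coverage_cpg_excluded_from_pool(self, config):
        g = annotated_gene(start=10000)
        w = promoter_window(g, flank_bp=500)
        # the 4-read CpG (fully methylated) is below min_cov=5: pooled
        # mean must equal the remaining 15/30
        s = make_sample([(9600, 4, 0), (9700, 5, 5), (9800, 5, 5), (9900, 5, 5)])
        assert summarize_promoter(s, g, w, config).mean_meth_percent == pytest.approx(50.0)


def window_sample(levels_pct, sample_id, origin, depth=10, n_cpgs=5):
    cpgs = [(9500 + 100 * j, int(round(depth * levels_pct / 100)),
             depth - int(round(depth * levels_pct / 100))) for j in range(n_cpgs)]
    return make_sample(cpgs, sample_id=sample_id, origin=origin)


class TestRankTests:
    WINDOW = GenomicInterval("chr1", 9500, 10500)

    def groups(self, ag_levels, pg_levels, **kw):
        ag = [window_sample(v, f"ag{i}", "androgenetic", **kw) for i, v in enumerate(ag_levels)]
        pg = [window_sample(v, f"pg{i}", "parthenogenetic", **kw) for i, v in enumerate(pg_levels)]
        return ag, pg

    def test_sample_mean_fully_separated_4v4(self, config):
        # the minimum attainable two-sided p for a 4v4 rank-sum is 2/70
        ag, pg = self.groups([90, 92, 88, 91], [10, 12, 8, 11], depth=100)
        p, delta = promoter_rank_test(ag, pg, self.WINDOW, config, mode="sample_mean")
        assert p == pytest.approx(2 / 70)
        assert delta == pytest.approx((90 + 92 + 88 + 91) / 4 - (10 + 12 + 8 + 11) / 4)
        assert p == pytest.approx(exact_ranksum_p([90, 92, 88, 91], [10, 12, 8, 11]))

    def test_identical_groups_p_one(self, config):
        ag, pg = self.groups([50, 50, 50, 50], [50, 50, 50, 50])
        p, delta = promoter_rank_test(ag, pg, self.WINDOW, config, mode="sample_mean")
        assert p == 1.0 and delta == 0.0

    def test_sample_mean_matches_enumeration_on_random_values(self, config):
        # tie-free draws: with ties the exact null is convention-dependent
        rng = np.random.default_rng(7)
        for _ in range(5):
            vals = rng.choice(np.arange(10, 90), size=7, replace=False)
            a, b = vals[:4], vals[4:]
            ag, pg = self.groups(a, b, depth=100)
            p, _ = promoter_rank_test(ag, pg, self.WINDOW, config, mode="sample_mean")
            assert p == pytest.approx(exact_ranksum_p(a, b))

    def test_cpg_level_complete_separation(self, config):
        # 20 CpGs x 4 samples per group, fully separated: the pooled
        # Mann-Whitney must be overwhelmingly significant
        ag, pg = self.groups([90, 91, 89, 92], [9, 10, 11, 8], depth=100, n_cpgs=20)
        p, delta = promoter_rank_test(ag, pg, self.WINDOW, config, mode="cpg_level")
        assert p < 1e-10 and delta > 75

    def test_cpg_level_agrees_with_exact_enumeration_small_case(self, config):
        # cross-check the pooled CpG-level path against full enumeration
        # on a tie-free 6v6 pool (3 CpGs x 2 samples per group)
        rng = np.random.default_rng(3)
        depth = 1000
        vals = rng.choice(np.arange(100, 900), size=12, replace=False)
        a_vals, b_vals = vals[:6], vals[6:]

        def build(vv, prefix, origin):
            return [
                make_sample(
                    [(9600 + 100 * j, vv[3 * i + j], depth - vv[3 * i + j]) for j in range(3)],
                    sample_id=f"{prefix}{i}", origin=origin,
                )
                for i in range(2)
            ]

        ag = build(a_vals, "a", "androgenetic")
        pg = build(b_vals, "p", "parthenogenetic")
        p, _ = promoter_rank_test(ag, pg, self.WINDOW, config, mode="cpg_level")
        expected = exact_ranksum_p(a_vals / depth, b_vals / depth)
        assert p == pytest.approx(expected, rel=0.1)

    def test_skips_when_fewer_than_two_informative(self, config):
        ag, pg = self.groups([90], [10, 12])
        assert promoter_rank_test(ag, pg, self.WINDOW, config) is None

    def test_label_swap_flips_delta_keeps_p(self, config):
        ag, pg = self.groups([80, 85, 82, 88], [20, 25, 22, 28], depth=100)
        p1, d1 = promoter_rank_test(ag, pg, self.WINDOW, config)
        p2, d2 = promoter_rank_test(pg, ag, self.WINDOW, config)
        assert p1 == pytest.approx(p2) and d1 == pytest.approx(-d2)


class TestCalling:
    def test_bh_hand_computation(self, config):
        # BH on [0.001, 0.02, 0.9]: q = [0.003, 0.03, 0.9]
        w = GenomicInterval("chr1", 0, 1000)
        tests = {
            "G1": (w, 0.001, 60.0),
            "G2": (w, 0.02, -40.0),
            "G3": (w, 0.9, 1.0),
        }
        calls = call_promoter_dmrs(tests, config)
        by_gene = {c.gene_id: c for c in calls}
        assert set(by_gene) == {"G1", "G2"}
        assert by_gene["G1"].q_value == pytest.approx(0.003)
        assert by_gene["G2"].q_value == pytest.approx(0.03)
        assert by_gene["G1"].direction == "paternal"
        assert by_gene["G2"].direction == "maternal"

    def test_all_null_no_calls(self, config):
        w = GenomicInterval("chr1", 0, 1000)
        assert call_promoter_dmrs({f"G{i}": (w, 1.0, 0.0) for i in range(5)}, config) == []

    def test_effect_size_gate(self, config):
        # significant q but a 10pp delta stays below the 25pp gate
        w = GenomicInterval("chr1", 0, 1000)
        assert call_promoter_dmrs({"G1": (w, 1e-6, 10.0)}, config) == []

    def test_empty_input(self, config):
        assert call_promoter_dmrs({}, config) == []

    def test_q_geq_p_and_monotone(self, config):
        w = GenomicInterval("chr1", 0, 1000)
        rng = np.random.default_rng(0)
        pvals = rng.random(30)
        tests = {f"G{i:02d}": (w, p, 60.0) for i, p in enumerate(pvals)}
        from imprintscan._stats import bh_qvalues

        q = bh_qvalues(pvals)
        assert (q >= pvals - 1e-12).all()
        order = np.argsort(pvals)
        assert (np.diff(q[order]) >= -1e-12).all()
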