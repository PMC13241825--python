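"""Germline-DMR scan: tiling, permutation test vs brute force, persistence."""

from math import comb

import numpy as np
import pytest

from imprintscan._stats import permutation_test
from imprintscan.config import PipelineConfig
from imprintscan.gdmr import (
    GdmrCall,
    call_gdmrs,
    classify_dmr_origin,
    make_scan_region,
    make_windows,
    persistence_check,
    scan_windows,
)
from imprintscan.model import DMRCall, GeneAnnotation, GenomicInterval, Transcript
from conftest import make_sample


def brute_force_perm_p(a, b):
    """Independent oracle: iterate every bitmask of group-A membership."""
    pooled = np.concatenate([a, b]).astype(float)
    n, na = len(pooled), len(a)
    obs = abs(np.mean(a) - np.mean(b))
    count = total = 0
    for mask in range(1 << n):
        if bin(mask).count("1") != na:
            continue
        sel = [(mask >> i) & 1 == 1 for i in range(n)]
        ga = pooled[sel]
        gb = pooled[[not s for s in sel]]
        total += 1
        if abs(ga.mean() - gb.mean()) >= obs - 1e-12:
            count += 1
    return count / total


class TestScanRegion:
    def annotation(self):
        def gene(gid, chrom, start, end):
            return GeneAnnotation(gid, gid, [Transcript(f"{gid}.t", GenomicInterval(chrom, start, end, "+"))])

        return {
            "A": gene("A", "chr19", 1_000_000, 1_050_000),
            "B": gene("B", "chr19", 1_250_000, 1_300_000),
            "C": gene("C", "chr2", 500, 900),
        }

    def test_span_plus_flank(self):
        r = make_scan_region(["A", "B"], 200_000, self.annotation())
        assert (r.start, r.end) == (800_000, 1_500_000)

    def test_zero_flank_is_anchor_span(self):
        r = make_scan_region(["A", "B"], 1, self.annotation())
        assert (r.start, r.end) == (999_999, 1_300_001)

    def test_single_anchor(self):
        r = make_scan_region(["A"], 100_000, self.annotation())
        assert (r.start, r.end) == (900_000, 1_150_000)

    def test_cross_chromosome_anchors_rejected(self):
        with pytest.raises(ValueError, match="chromosome"):
            make_scan_region(["A", "C"], 1000, self.annotation())

    def test_missing_anchor(self):
        with pytest.raises(KeyError):
            make_scan_region(["Z"], 1000, self.annotation())


class TestWindows:
    def test_grid_tiling_with_short_last(self):
        tiles = make_windows(GenomicInterval("chr1", 0, 3500), 1000)
        assert [(t.start, t.end) for t in tiles] == [(0, 1000), (1000, 2000), (2000, 3000), (3000, 3500)]

    def test_single_window(self):
        tiles = make_windows(GenomicInterval("chr1", 2000, 3000), 1000)
        assert [(t.start, t.end) for t in tiles] == [(2000, 3000)]

    def test_tiles_reassemble_region_exactly(self):
        region = GenomicInterval("chr1", 12345, 99999)
        tiles = make_windows(region, 1000)
        assert tiles[0].start == region.start and tiles[-1].end == region.end
        for t1, t2 in zip(tiles, tiles[1:]):
            assert t1.end == t2.start
        assert sum(len(t) for t in tiles) == len(region)

    def test_every_position_in_exactly_one_tile(self):
        region = GenomicInterval("chr1", 500, 4200)
        tiles = make_windows(region, 1000)
        rng = np.random.default_rng(0)
        for pos in rng.integers(region.start, region.end, 50):
            assert sum(t.start <= pos < t.end for t in tiles) == 1


class TestPermutationTest:
    def test_4v3_fixture_strict_maximum(self):
        # observed statistic is the strict maximum among C(7,3)=35 splits
        p = permutation_test(np.array([80, 85, 90, 82]), np.array([10, 12, 8]))
        assert p == pytest.approx(1 / 35)

    def test_identical_constants_p_one(self):
        assert permutation_test(np.full(4, 55.0), np.full(3, 55.0)) == 1.0

    @pytest.mark.parametrize("na,nb", [(1, 1), (2, 2), (3, 2), (4, 3), (5, 4), (6, 6), (2, 6)])
    def test_exact_matches_brute_force(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        for _ in range(3):
            a = rng.normal(50, 20, na)
            b = rng.normal(55, 20, nb)
            assert permutation_test(a, b) == pytest.approx(brute_force_perm_p(a, b))

    def test_label_exchange_invariance(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(40, 10, 4), rng.normal(60, 10, 5)
        assert permutation_test(a, b) == pytest.approx(permutation_test(b, a))

    def test_monte_carlo_close_to_exact(self):
        a = np.array([80.0, 85, 90, 82])
        b = np.array([10.0, 12, 8])
        exact = permutation_test(a, b)
        n_mc = 10_000
        mc = permutation_test(a, b, max_exact=10, n_mc=n_mc, rng=np.random.default_rng(5))
        se = np.sqrt(exact * (1 - exact) / n_mc)
        assert abs(mc - exact) <= 3 * se + 2 / n_mc

    def test_p_floor_is_one_over_n_assignments(self):
        a = np.array([100.0, 99, 98, 97])
        b = np.array([0.0, 1, 2])
        assert permutation_test(a, b) >= 1 / comb(7, 3)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_test(np.array([1.0]), np.array([]))


def germ_sample(window_levels, sample_id, origin, depth=20):
    """Sample with 4 CpGs in each 1-kb window [k*1000, (k+1)*1000)."""
    cpgs = []
    for k, pct in enumerate(window_levels):
        if pct is None:
            continue
        for j in range(4):
            meth = int(round(depth * pct / 100))
            cpgs.append((k * 1000 + 100 + 200 * j, meth, depth - meth))
    return make_sample(cpgs, sample_id=sample_id, origin=origin, stage="germ", chrom="chrG")


class TestScanAndCalls:
    def build(self, sperm_levels, oocyte_levels, n_windows):
        sperm = [germ_sample(lv, f"sp{i}", "sperm") for i, lv in enumerate(sperm_levels)]
        oocyte = [germ_sample(lv, f"oo{i}", "oocyte") for i, lv in enumerate(oocyte_levels)]
        region = GenomicInterval("chrG", 0, n_windows * 1000)
        return scan_windows(sperm, oocyte, region, PipelineConfig())

    def test_single_extreme_window_cannot_pass_bh_alone(self, config):
        # one window at the 4v3 enumeration floor p=1/35 among 34 nulls:
        # BH gives q = 1/35 * 35 / 1 = 1.0 -> no call
        sperm_levels = [[90, *([50] * 34)]] * 4
        oocyte_levels = [[10, *([50] * 34)]] * 3
        windows = self.build(sperm_levels, oocyte_levels, 35)
        extreme = windows[0]
        assert extreme.p_perm == pytest.approx(1 / 35)
        assert extreme.q > config.dmr_alpha
        assert call_gdmrs(windows, config) == []

    def test_small_universe_allows_calls(self, config):
        # 3 of 5 tested windows at the floor: q = 5/3 * 1/35 = 0.0476 <= 0.05
        sperm_levels = [[90, 90, 10, 50, 50]] * 4
        oocyte_levels = [[10, 10, 90, 50, 50]] * 3
        windows = self.build(sperm_levels, oocyte_levels, 5)
        calls = call_gdmrs(windows, config)
        assert len(calls) == 3
        dirs = {c.window.start: c.germ_direction for c in calls}
        assert dirs[0] == "sperm_methylated" and dirs[2000] == "oocyte_methylated"
        for c in calls:
            assert c.q == pytest.approx(5 / 3 / 35)

    def test_uncovered_windows_excluded_from_universe(self, config):
        sperm_levels = [[90, None, 50]] * 4
        oocyte_levels = [[10, None, 50]] * 3
        windows = self.build(sperm_levels, oocyte_levels, 3)
        assert windows[1].p_perm is None and windows[1].q is None
        assert sum(w.p_perm is not None for w in windows) == 2

    def test_empty_input(self, config):
        assert call_gdmrs([], config) == []


class TestPersistenceAndOrigin:
    def call_at(self, direction="oocyte_methylated"):
        return GdmrCall(
            window=GenomicInterval("chrG", 0, 1000),
            germ_direction=direction,
            delta_pp=-80.0 if direction == "oocyte_methylated" else 80.0,
            p_perm=1 / 35,
            q=0.04,
        )

    def uni(self, ag_levels, pg_levels):
        ag = [germ_sample([v], f"ag{i}", "androgenetic") for i, v in enumerate(ag_levels)]
        pg = [germ_sample([v], f"pg{i}", "parthenogenetic") for i, v in enumerate(pg_levels)]
        return ag, pg

    def test_concordant_persistence(self, config):
        ag, pg = self.uni([8, 10, 12, 9], [90, 88, 92, 91])
        call = persistence_check(self.call_at("oocyte_methylated"), ag, pg, config)
        assert call.persistent and call.origin_class == "germline_candidate"
        assert call.persistence_p == pytest.approx(2 / 70)

    def test_discordant_direction_not_persistent(self, config):
        # oocyte-methylated in gametes but AG-hypermethylated in hESCs
        ag, pg = self.uni([90, 88, 92, 91], [8, 10, 12, 9])
        call = persistence_check(self.call_at("oocyte_methylated"), ag, pg, config)
        assert not call.persistent and call.origin_class == "germline_non_persistent"

    def test_flat_methylation_not_persistent(self, config):
        ag, pg = self.uni([50, 50, 50, 50], [50, 50, 50, 50])
        assert not persistence_check(self.call_at(), ag, pg, config).persistent

    def test_origin_classification(self):
        germ = [self.call_at("oocyte_methylated")]
        inside = DMRCall("G1", GenomicInterval("chrG", 500, 1500), "maternal", -60.0, 1e-4, 1e-3, "cpg_level")
        outside = DMRCall("G2", GenomicInterval("chrG", 5000, 6000), "maternal", -60.0, 1e-4, 1e-3, "cpg_level")
        discordant = DMRCall("G3", GenomicInterval("chrG", 500, 1500), "paternal", 60.0, 1e-4, 1e-3, "cpg_level")
        out = classify_dmr_origin([inside, outside, discordant], germ)
        assert out == {"G1": "germline_derived", "G2": "secondary", "G3": "secondary"}
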