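"""ORC analyses: sharing, density, depletion, free zones, low-density domains."""

import numpy as np
import pytest

from polyrep.genome import GenomeLayout, GInterval, IntervalSet, PointSet
from polyrep.orc import (
    depletion_test,
    low_density_domains,
    orc_density,
    orc_free_zone,
    share_classes,
    urs_with_orc,
)

from conftest import random_interval_set, random_point_set


class TestShareClasses:
    def test_summits_900bp_apart_shared(self):
        a = PointSet({"c": [10_000]})
        b = PointSet({"c": [10_900]})
        df = share_classes([("A", a), ("B", b)])
        assert len(df) == 1
        assert df.iloc[0]["tissues"] == ("A", "B")

    def test_summits_1100bp_apart_unique(self):
        a = PointSet({"c": [10_000]})
        b = PointSet({"c": [11_100]})
        df = share_classes([("A", a), ("B", b)])
        assert len(df) == 2
        assert set(df["n_shared"]) == {0}

    def test_boundary_exactly_radius_is_shared(self):
        df = share_classes([("A", PointSet({"c": [0]})), ("B", PointSet({"c": [1_000]}))])
        assert len(df) == 1

    def test_random_partition_matches_closure_oracle(self, rng):
        genome = GenomeLayout({"c": 200_000})
        sets = [(f"t{i}", random_point_set(rng, genome, 30)) for i in range(5)]
        df = share_classes(sets, radius=1_000)
        # oracle: transitive closure over all pooled summits
        pooled = sorted(
            (int(p), name) for name, pts in sets for p in pts.get("c")
        )
        oracle_clusters = []
        cur = [pooled[0]]
        for item in pooled[1:]:
            if item[0] - cur[-1][0] <= 1_000:
                cur.append(item)
            else:
                oracle_clusters.append(cur)
                cur = [item]
        oracle_clusters.append(cur)
        assert len(df) == len(oracle_clusters)
        got = sorted(tuple(sorted({n for _, n in c})) for c in oracle_clusters)
        assert sorted(df["tissues"].map(tuple)) == got


class TestDensity:
    def test_ten_peaks_in_one_mb(self):
        peaks = PointSet({"c": np.arange(0, 1_000_000, 100_000)})
        regions = IntervalSet.from_records([("c", 0, 1_000_000)])
        assert orc_density(peaks, regions) == pytest.approx(1.0)

    def test_no_peaks_zero_density(self):
        regions = IntervalSet.from_records([("c", 0, 100_000)])
        assert orc_density(PointSet(), regions) == 0.0

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            orc_density(PointSet(), IntervalSet())

    def test_random_case_matches_scan_oracle(self, rng, toy_genome):
        peaks = random_point_set(rng, toy_genome, 300)
        regions = random_interval_set(rng, toy_genome, 20)
        expected = sum(
            1
            for chrom, arr in peaks.items()
            for p in arr
            if any(s <= p < e for s, e in regions.get(chrom))
        )
        got = orc_density(peaks, regions)
        assert got == pytest.approx(expected * 100_000 / regions.coverage_bp)


class TestDepletionTest:
    def test_symmetric_case_p_near_half(self):
        # uniform peaks, one UR covering exactly the structure-free genome
        genome = GenomeLayout({"c": 1_000_000})
        rng = np.random.default_rng(0)
        peaks = PointSet({"c": np.sort(rng.integers(0, 1_000_000, 200))})
        urs = IntervalSet.from_records([("c", 400_000, 600_000)])
        res = depletion_test(peaks, urs, genome, n_perm=4_000, seed=1)
        assert 0.1 < res.p_value < 1.0  # central, not extreme

    def test_planted_depletion_detected(self):
        # several peak-free URs: a null total of 0 is then essentially
        # impossible under random placement, so depletion is unambiguous
        genome = GenomeLayout({"c": 4_000_000})
        rng = np.random.default_rng(2)
        urs = IntervalSet.from_records(
            [("c", s, s + 150_000) for s in range(500_000, 3_500_000, 600_000)]
        )
        pts = np.sort(rng.integers(0, 4_000_000, 800))
        keep = ~urs.contains_points("c", pts)
        res = depletion_test(
            PointSet({"c": pts[keep]}), urs, genome, n_perm=10_000, seed=3
        )
        assert res.observed == 0
        assert res.p_value <= 0.001

    def test_reproducible_given_seed(self, toy_genome, rng):
        peaks = random_point_set(rng, toy_genome, 100)
        urs = random_interval_set(rng, toy_genome, 10)
        a = depletion_test(peaks, urs, toy_genome, n_perm=500, seed=9)
        b = depletion_test(peaks, urs, toy_genome, n_perm=500, seed=9)
        assert a.p_value == b.p_value and a.null_mean == b.null_mean

    def test_ur_wider_than_chromosome_rejected(self):
        genome = GenomeLayout({"c": 1_000})
        urs = IntervalSet.from_records([("c", 0, 1_000)])
        peaks = PointSet({"c": [10]})
        res = depletion_test(peaks, urs, genome, n_perm=10, seed=0)
        assert res.observed == 1  # full-width is allowed; wider cannot exist


class TestORCFreeZone:
    def test_flanking_sites_define_zone(self):
        ur = GInterval("c", 450_000, 550_000)  # midpoint 500,000
        peaks = PointSet({"c": [400_000, 650_000]})
        z = orc_free_zone(ur, peaks)
        assert (z.left_site, z.right_site) == (400_000, 650_000)
        assert z.zone_width == 250_000

    def test_missing_left_side_is_none(self):
        ur = GInterval("c", 0, 100_000)
        z = orc_free_zone(ur, PointSet({"c": [200_000]}))
        assert z.left_site is None and z.zone_width is None
        assert z.right_site == 200_000

    def test_summit_at_midpoint_counts_right(self):
        ur = GInterval("c", 0, 1_000)  # midpoint 500
        z = orc_free_zone(ur, PointSet({"c": [100, 500]}))
        assert z.right_site == 500 and z.left_site == 100

    def test_orc_free_ur_zone_at_least_ur_width(self, rng, toy_genome):
        for _ in range(50):
            urs = random_interval_set(rng, toy_genome, 5)
            peaks = random_point_set(rng, toy_genome, 40)
            for iv in urs:
                inside = peaks.counts_per_interval(
                    IntervalSet.from_intervals([iv])
                )[0]
                z = orc_free_zone(iv, peaks)
                if inside == 0 and z.zone_width is not None:
                    assert z.zone_width >= iv.width - 1


class TestLowDensityDomains:
    def test_empty_chromosome_is_one_domain(self):
        genome = GenomeLayout({"c": 600_000})
        domains, table = low_density_domains(PointSet(), genome)
        assert domains.to_records() == [("c", 0, 600_000)]
        assert list(table["n_peaks"]) == [0]

    def test_dense_background_with_one_gap(self):
        genome = GenomeLayout({"c": 2_000_000})
        # peaks every 10 kb except a 400-kb hole at [800k, 1.2M)
        pts = np.arange(0, 2_000_000, 10_000)
        pts = pts[(pts < 800_000) | (pts >= 1_200_000)]
        domains, _ = low_density_domains(PointSet({"c": pts}), genome)
        assert len(domains) == 1
        (dom,) = list(domains)
        # the domain covers the gap's interior up to window granularity
        assert dom.start <= 900_000 and dom.end >= 1_100_000
        assert 800_000 - 150_000 <= dom.start and dom.end <= 1_200_000 + 150_000

    def test_window_edge_membership_half_open(self):
        genome = GenomeLayout({"c": 300_000})
        # 2 peaks in every window except the peak exactly at 150,000 belongs
        # to the window starting at 150,000, not the one ending there
        pts = [10, 20, 75_010, 75_020, 150_000]
        domains, table = low_density_domains(
            PointSet({"c": pts}), genome, window=150_000, step=75_000
        )
        counts = {(r.start, r.end): r.n_peaks for r in table.itertuples()}
        assert len(domains) >= 1

    def test_matches_brute_force_enumeration(self, rng):
        genome = GenomeLayout({"c": 2_000_000})
        for _ in range(10):
            pts = np.sort(rng.integers(0, 2_000_000, int(rng.integers(0, 120))))
            domains, _ = low_density_domains(PointSet({"c": pts}), genome)
            # independent loop-based oracle
            kept = []
            start = 0
            while start < 2_000_000:
                end = min(start + 150_000, 2_000_000)
                n = sum(1 for p in pts if start <= p < end)
                if n <= 1:
                    kept.append((start, end))
                start += 75_000
            merged = []
            for s, e in kept:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            assert domains.to_records() == [("c", s, e) for s, e in merged]

    def test_window_step_mismatch_rejected(self):
        with pytest.raises(ValueError):
            low_density_domains(PointSet(), GenomeLayout({"c": 1_000}), 100, 33)


class TestUrsWithOrc:
    def test_all_empty(self):
        urs = IntervalSet.from_records([("c", 0, 100), ("c", 200, 300)])
        frac, occupied = urs_with_orc(urs, PointSet())
        assert frac == 0.0 and occupied == []

    def test_all_occupied(self):
        urs = IntervalSet.from_records([("c", 0, 100), ("c", 200, 300)])
        frac, occupied = urs_with_orc(urs, PointSet({"c": [50, 250]}))
        assert frac == 1.0 and len(occupied) == 2

    def test_random_matches_scan_oracle(self, rng, toy_genome):
        urs = random_interval_set(rng, toy_genome, 15)
        peaks = random_point_set(rng, toy_genome, 60)
        frac, occupied = urs_with_orc(urs, peaks)
        expected = [
            iv
            for iv in urs
            if any(iv.start <= p < iv.end for p in peaks.get(iv.chrom))
        ]
        assert occupied == expected
        assert frac == pytest.approx(len(expected) / len(urs))
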