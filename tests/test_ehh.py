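from fractions import Fraction

import numpy as np
import pytest

from rehhscan.cores import CoreAllele, CoreRegion, core_alleles
from rehhscan.ehh import (DOWNSTREAM, UPSTREAM, REHH_INF, bifurcation, ehh_at,
                          ehh_decay, ehh_pooled_others, rehh, nearest_test_marker)
from rehhscan.errors import MissingMarkerError, UndefinedStatisticError

from conftest import make_hapset, make_map

# ---------------------------------------------------------------------------
# Oracle: probability that two distinct random carriers are identical over the
# interval, by exact all-pairs scan in rational arithmetic.
# ---------------------------------------------------------------------------


def oracle_ehh(matrix) -> Fraction:
    matrix = np.asarray(matrix)
    c = matrix.shape[0]
    same = 0
    for i in range(c):
        for j in range(i + 1, c):
            if np.array_equal(matrix[i], matrix[j]):
                same += 1
    return Fraction(same, c * (c - 1) // 2)


def oracle_pooled(groups) -> Fraction:
    num = 0
    den = 0
    for g in groups:
        c = g.shape[0]
        den += c * (c - 1) // 2
        for i in range(c):
            for j in range(i + 1, c):
                if np.array_equal(g[i], g[j]):
                    num += 1
    return Fraction(num, den)


def allele_for(hs, start, end, allele_string):
    region = CoreRegion("1", start, end, 1, 1)
    for a in core_alleles(region, hs):
        if a.allele == allele_string:
            return a, core_alleles(region, hs)
    raise AssertionError("allele not found")


class TestEhhAt:
    def test_four_carriers_split_2_2(self):
        ext = np.array([[0], [0], [1], [1]])
        assert ehh_at(ext) == pytest.approx(2 / 6)

    def test_all_identical(self):
        ext = np.zeros((5, 4), dtype=int)
        assert ehh_at(ext) == 1.0

    def test_five_carriers_split_3_1_1(self):
        ext = np.array([[0, 0], [0, 0], [0, 0], [0, 1], [1, 0]])
        assert ehh_at(ext) == pytest.approx(3 / 10)

    def test_singleton_errors(self):
        with pytest.raises(UndefinedStatisticError):
            ehh_at(np.zeros((1, 3), dtype=int))

    def test_matches_pair_scan_oracle(self, rng):
        for _ in range(200):
            c = int(rng.integers(2, 50))
            m = int(rng.integers(1, 30))
            ext = rng.integers(0, 2, (c, m))
            assert ehh_at(ext) == pytest.approx(float(oracle_ehh(ext)), abs=1e-12)


class TestPooled:
    def test_two_conserved_other_alleles(self):
        groups = [np.zeros((3, 2), dtype=int), np.ones((3, 2), dtype=int)]
        assert ehh_pooled_others(groups) == 1.0

    def test_all_distinct_extensions(self):
        g = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        assert ehh_pooled_others([g]) == 0.0

    def test_mixed_case_3_over_7(self):
        s1 = np.array([[0], [0], [1], [1]])     # split 2/2 -> 2 pairs
        s2 = np.array([[0], [0]])               # identical -> 1 pair
        assert ehh_pooled_others([s1, s2]) == pytest.approx(3 / 7)

    def test_cross_allele_identity_not_counted(self):
        # same extension strings but different core alleles: never homozygous
        s1 = np.array([[0], [0]])
        s2 = np.array([[0], [0]])
        val = ehh_pooled_others([s1, s2])
        assert val == pytest.approx(2 / 2)  # pairs only within each allele

    def test_matches_oracle(self, rng):
        for _ in range(50):
            groups = [rng.integers(0, 2, (int(rng.integers(1, 8)), 4)) for _ in range(3)]
            if sum(g.shape[0] for g in groups) < 2:
                continue
            assert ehh_pooled_others(groups) == pytest.approx(float(oracle_pooled(groups)), abs=1e-12)


class TestEhhDecay:
    def make_core(self, hap, start, end):
        hs = make_hapset(hap)
        mm = make_map(hap.shape[1], spacing_bp=100_000)
        region = CoreRegion("1", start, end, int(mm.pos_bp[start]), int(mm.pos_bp[end]))
        alleles = core_alleles(region, hs)
        return hs, mm, alleles

    def test_core_at_chromosome_end_empty_curve(self, rng):
        hap = np.tile(rng.integers(0, 2, 6)[:, None], (1, 3)).astype(np.uint8)
        hs, mm, alleles = self.make_core(hap, 0, 2)
        curve = ehh_decay(hs, mm, alleles[0], DOWNSTREAM)
        assert len(curve.ehh) == 0  # edge value 1 is implicit

    def test_identical_carriers_ehh_one_to_end(self, rng):
        carrier = rng.integers(0, 2, 8)
        hap = np.tile(carrier[:, None], (1, 10)).astype(np.uint8)
        hs, mm, alleles = self.make_core(hap, 4, 5)
        for direction in (UPSTREAM, DOWNSTREAM):
            curve = ehh_decay(hs, mm, alleles[0], direction, stop_ehh=0.05)
            assert np.all(curve.ehh == 1.0)
            assert len(curve.ehh) == 4

    def test_monotone_nonincreasing(self, sim_population):
        hs, mm = sim_population
        from rehhscan.cores import find_cores
        regions = find_cores(hs, mm)
        checked = 0
        for region in regions[:10]:
            for allele in core_alleles(region, hs):
                if allele.count < 2:
                    continue
                curve = ehh_decay(hs, mm, allele, DOWNSTREAM, stop_ehh=0.0)
                assert np.all(np.diff(curve.ehh) <= 1e-12)
                checked += 1
        assert checked > 5

    def test_curve_matches_bruteforce_oracle(self, rng):
        hap = rng.integers(0, 2, (200, 20)).astype(np.uint8)
        hap[:, 8:12] = hap[:, [8]]  # forced core
        hs, mm, alleles = self.make_core(hap, 8, 11)
        allele = alleles[0]
        curve = ehh_decay(hs, mm, allele, DOWNSTREAM, stop_ehh=0.0)
        for k, j in enumerate(curve.marker_idx):
            sub = hs.hap[np.ix_(allele.carrier_rows, np.arange(12, j + 1))]
            assert curve.ehh[k] == pytest.approx(float(oracle_ehh(sub)), abs=1e-12)

    def test_stops_below_threshold(self, rng):
        hap = rng.integers(0, 2, (60, 30)).astype(np.uint8)
        hap[:, 0:3] = hap[:, [0]]
        hs, mm, alleles = self.make_core(hap, 0, 2)
        curve = ehh_decay(hs, mm, alleles[0], DOWNSTREAM, stop_ehh=0.05)
        if curve.ehh[-1] < 0.05:  # stopping sample included, nothing beyond
            assert np.all(curve.ehh[:-1] >= 0.05)


class TestRehh:
    def build(self, rng, n_hap=40, m=21, core=(9, 11)):
        hap = rng.integers(0, 2, (n_hap, m)).astype(np.uint8)
        hap[:, core[0]:core[1] + 1] = np.tile(rng.integers(0, 2, n_hap)[:, None],
                                              (1, core[1] - core[0] + 1))
        hs = make_hapset(hap)
        mm = make_map(m, spacing_bp=50_000)
        region = CoreRegion("1", core[0], core[1], int(mm.pos_bp[core[0]]), int(mm.pos_bp[core[1]]))
        return hs, mm, core_alleles(region, hs)

    def test_test_marker_nearest_and_tie_farther(self):
        mm = make_map(11, spacing_bp=100_000)  # 0.1 cM spacing
        region = CoreRegion("1", 5, 5, int(mm.pos_bp[5]), int(mm.pos_bp[5]))
        # distances downstream: 0.1, 0.2, 0.3 ... -> nearest to 0.25 is tie 0.2/0.3 -> farther
        j = nearest_test_marker(region, mm, DOWNSTREAM, test_distance_cm=0.25)
        assert j == 8  # 0.3 cM away

    def test_missing_marker_error_when_sparse(self):
        mm = make_map(2, spacing_bp=5_000_000)  # 5 cM apart
        region = CoreRegion("1", 0, 0, int(mm.pos_bp[0]), int(mm.pos_bp[0]))
        with pytest.raises(MissingMarkerError):
            nearest_test_marker(region, mm, DOWNSTREAM, test_distance_cm=0.25)

    def test_equal_ehh_gives_one(self, rng):
        hs, mm, alleles = self.build(rng)
        # identical flank content for everyone -> EHH_t == EHH_pooled == 1
        hap = hs.hap.copy()
        hap[:, :9] = 0
        hap[:, 12:] = 0
        hs2 = make_hapset(hap)
        region = alleles[0].region
        alleles2 = core_alleles(region, hs2)
        rv = rehh(hs2, mm, alleles2, 0, DOWNSTREAM)
        assert rv.rehh == pytest.approx(1.0)

    def test_ratio_value(self, rng):
        hs, mm, alleles = self.build(rng, n_hap=60)
        rv = rehh(hs, mm, alleles, 0, DOWNSTREAM)
        assert rv.rehh == pytest.approx(rv.ehh_t / rv.ehh_pooled)

    def test_infinite_sentinel(self):
        # carriers identical downstream; all others mutually distinct there
        n = 8
        hap = np.zeros((2 * n, 6), dtype=np.uint8)
        hap[:n, 0] = 0   # core = marker 0; carriers of allele 0
        hap[n:, 0] = 1
        # downstream markers: carriers all zero; others pairwise distinct
        for k in range(n):
            hap[n + k, 1:6] = [(k >> b) & 1 for b in range(5)]
        hs = make_hapset(hap)
        mm = make_map(6, spacing_bp=50_000)
        region = CoreRegion("1", 0, 0, int(mm.pos_bp[0]), int(mm.pos_bp[0]))
        alleles = core_alleles(region, hs)
        t = next(i for i, a in enumerate(alleles) if a.allele == "0")
        rv = rehh(hs, mm, alleles, t, DOWNSTREAM)
        assert rv.rehh == REHH_INF

    def test_symmetric_two_allele_region(self):
        # two equally frequent alleles with mirrored extension structure
        hap = np.array([
            [0, 0, 0], [0, 0, 0], [0, 0, 1], [0, 0, 1],
            [1, 1, 0], [1, 1, 0], [1, 1, 1], [1, 1, 1],
        ], dtype=np.uint8)
        hs = make_hapset(hap)
        mm = make_map(3, spacing_bp=250_000)
        region = CoreRegion("1", 0, 1, int(mm.pos_bp[0]), int(mm.pos_bp[1]))
        alleles = core_alleles(region, hs)
        r0 = rehh(hs, mm, alleles, 0, DOWNSTREAM)
        r1 = rehh(hs, mm, alleles, 1, DOWNSTREAM)
        assert r0.rehh == pytest.approx(1.0)
        assert r1.rehh == pytest.approx(1.0)

    def test_relabeling_invariance(self, rng):
        hs, mm, alleles = self.build(rng, n_hap=60)
        rv = rehh(hs, mm, alleles, 0, DOWNSTREAM)
        flipped = hs.hap.copy()
        flipped[:, 15] = 1 - flipped[:, 15]
        hs2 = make_hapset(flipped)
        alleles2 = core_alleles(alleles[0].region, hs2)
        rv2 = rehh(hs2, mm, alleles2, 0, DOWNSTREAM)
        assert rv2.rehh == pytest.approx(rv.rehh)
        assert rv2.ehh_t == pytest.approx(rv.ehh_t)

    def test_log_rehh_symmetric_under_balanced_alleles(self, rng):
        """Two equal-frequency alleles with i.i.d. flanks: sign of log rEHH is fair."""
        from scipy.stats import binomtest

        signs = []
        for rep in range(200):
            local = np.random.default_rng(rep)
            n = 10
            core = np.repeat([0, 1], n)[:, None]
            flanks = local.integers(0, 2, (2 * n, 8))
            hap = np.hstack([core, flanks]).astype(np.uint8)
            hs = make_hapset(hap)
            mm = make_map(9, spacing_bp=50_000)
            region = CoreRegion("1", 0, 0, int(mm.pos_bp[0]), int(mm.pos_bp[0]))
            alleles = core_alleles(region, hs)
            rv = rehh(hs, mm, alleles, 0, DOWNSTREAM)
            if np.isfinite(rv.rehh) and rv.rehh > 0 and rv.rehh != 1.0:
                signs.append(rv.rehh > 1.0)
        test = binomtest(sum(signs), len(signs), 0.5)
        assert test.pvalue > 0.01


class TestBifurcation:
    def test_identical_carriers_path_graph(self):
        hap = np.zeros((6, 5), dtype=np.uint8)
        hs = make_hapset(hap)
        mm = make_map(5)
        region = CoreRegion("1", 0, 0, 1, 1)
        allele = core_alleles(region, hs)[0]
        tree = bifurcation(hs, mm, allele, DOWNSTREAM, max_markers=4)
        node = tree.root
        depth = 0
        while node.children:
            assert len(node.children) == 1
            node = next(iter(node.children.values()))
            depth += 1
        assert depth == 4

    def test_first_marker_split_2_2(self):
        hap = np.zeros((4, 3), dtype=np.uint8)
        hap[2:, 1] = 1
        hs = make_hapset(hap)
        mm = make_map(3)
        region = CoreRegion("1", 0, 0, 1, 1)
        allele = core_alleles(region, hs)[0]
        tree = bifurcation(hs, mm, allele, DOWNSTREAM, max_markers=1)
        counts = sorted(c.count for c in tree.root.children.values())
        assert counts == [2, 2]

    def test_counts_conserved_at_every_depth(self, rng):
        hap = rng.integers(0, 2, (30, 10)).astype(np.uint8)
        hap[:, 0] = 0
        hs = make_hapset(hap)
        mm = make_map(10)
        region = CoreRegion("1", 0, 0, 1, 1)
        allele = core_alleles(region, hs)[0]
        tree = bifurcation(hs, mm, allele, DOWNSTREAM, max_markers=6)

        def check(node):
            if node.children:
                assert sum(c.count for c in node.children.values()) == node.count
                for c in node.children.values():
                    check(c)

        check(tree.root)
        assert tree.root.count == allele.count

    def test_json_serializable(self, rng):
        import json

        hap = rng.integers(0, 2, (10, 5)).astype(np.uint8)
        hap[:, 0] = 1
        hs = make_hapset(hap)
        mm = make_map(5)
        allele = core_alleles(CoreRegion("1", 0, 0, 1, 1), hs)[0]
        tree = bifurcation(hs, mm, allele, DOWNSTREAM, max_markers=3)
        json.dumps(tree.to_dict())


class TestEhhProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.integers(2, 25), st.integers(0, 8), st.integers(0, 2**20 - 1))
    @settings(max_examples=80, deadline=None)
    def test_ehh_matches_oracle_and_bounds(self, c, m, seed):
        rng = np.random.default_rng(seed)
        ext = rng.integers(0, 2, (c, m))
        val = ehh_at(ext)
        assert 0.0 <= val <= 1.0
        assert val == pytest.approx(float(oracle_ehh(ext)), abs=1e-12)
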