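import math

import numpy as np
import pytest

from clusterbench import (
    CaseVector,
    ScanStatistic,
    sss_detect,
    sss_llr,
    sss_zones,
)
from clusterbench.geography import DistrictMap
from conftest import square_lattice


def random_map(H: int, seed: int) -> DistrictMap:
    """Random connected map with generic centroids and populations."""
    rng = np.random.default_rng(seed)
    pts = rng.random((H, 2)) * 10
    W = np.zeros((H, H), dtype=int)
    for i in range(1, H):  # random tree keeps it connected
        j = int(rng.integers(i))
        W[i, j] = W[j, i] = 1
    for _ in range(H):
        i, j = rng.integers(H, size=2)
        if i != j:
            W[i, j] = W[j, i] = 1
    return DistrictMap(
        [f"R{i}" for i in range(H)], W, rng.integers(50, 500, H).astype(float), pts
    )


def brute_force_max_llr(dmap, cases, max_frac):
    """Exhaustive enumeration over all zones via the printed likelihood ratio."""
    best = 0.0
    for z in sss_zones(dmap, max_frac):
        D = int(cases.cases[list(z.members)].sum())
        best = max(best, sss_llr(D, z.U, cases.C, dmap.N))
    return best


class TestLLR:
    def test_observed_equals_expected_is_zero(self):
        assert sss_llr(5, 500, 10, 1000) == 0.0

    def test_deficit_is_zero_by_indicator(self):
        assert sss_llr(0, 500, 10, 1000) == 0.0

    def test_printed_example(self):
        val = sss_llr(5, 100, 10, 1000)
        assert val == pytest.approx(5 * math.log(5) + 5 * math.log(5 / 9), rel=1e-12)
        assert val == pytest.approx(5.108, abs=5e-4)

    def test_all_cases_in_zone(self):
        assert np.isfinite(sss_llr(10, 100, 10, 1000))

    def test_input_contract(self):
        with pytest.raises(ValueError):
            sss_llr(11, 100, 10, 1000)
        with pytest.raises(ValueError):
            sss_llr(5, 1000, 10, 1000)


class TestZones:
    def test_three_district_full_enumeration(self):
        dmap = random_map(3, seed=0)
        zones = sss_zones(dmap, max_frac=1.0)
        # nested prefixes from 3 centers; dedup keeps distinct member sets
        assert all(z.members[0] == z.center for z in zones)
        sets = {frozenset(z.members) for z in zones}
        assert frozenset(range(3)) in sets
        assert all(frozenset({i}) in sets for i in range(3))

    def test_population_cap_respected(self, german_like_map):
        cap = 0.10 * german_like_map.N
        for z in sss_zones(german_like_map, max_frac=0.10):
            assert z.U <= cap

    def test_membership_matches_brute_force(self):
        for seed in range(5):
            dmap = random_map(12, seed=seed)
            D = dmap.distance_matrix()
            cap = 0.4 * dmap.N
            expected = set()
            for i in range(dmap.H):
                ranked = sorted(
                    (j for j in range(dmap.H) if j != i), key=lambda j: (D[i, j], j)
                )
                members, U = [i], dmap.populations[i]
                if U <= cap:
                    expected.add(frozenset(members))
                    for j in ranked:
                        if U + dmap.populations[j] > cap:
                            break
                        members.append(j)
                        U += dmap.populations[j]
                        expected.add(frozenset(members))
            got = {frozenset(z.members) for z in sss_zones(dmap, max_frac=0.4)}
            assert got == expected


class TestDetect:
    def test_max_equals_brute_force_on_small_maps(self):
        for seed in range(8):
            dmap = random_map(20, seed=10 + seed)
            rng = np.random.default_rng(seed)
            e = dmap.populations * 20e-6 * 10
            cases = CaseVector(rng.poisson(e * 2), e)
            if cases.C == 0:
                continue
            res = ScanStatistic(dmap, cases, max_frac=0.4, n_mc=19, seed=1).fit()
            assert res.llr_max == pytest.approx(
                brute_force_max_llr(dmap, cases, 0.4), rel=1e-10
            )

    def test_piled_cases_most_likely_zone(self):
        dmap = square_lattice(4, populations=100.0)
        c = np.zeros(16, dtype=int)
        c[5] = 30
        cases = CaseVector(c, np.full(16, 2.0))
        res = ScanStatistic(dmap, cases, max_frac=0.5, n_mc=99, seed=0).fit()
        assert 5 in res.most_likely.members

    def test_no_cases_defined_result(self, german_like_map):
        e = german_like_map.populations * 7e-6 * 10
        cv = CaseVector(np.zeros(german_like_map.H, dtype=int), e)
        res = sss_detect(german_like_map, cv, n_mc=9)
        assert res.p_value == 1.0
        assert not res.labels.any()

    def test_pvalue_range_and_correction(self):
        dmap = square_lattice(4, populations=100.0)
        c = np.zeros(16, dtype=int)
        c[5] = 30
        cases = CaseVector(c, np.full(16, 2.0))
        res = ScanStatistic(dmap, cases, n_mc=99, max_frac=0.5, seed=0).fit()
        assert 1 / 100 <= res.p_value <= 1.0

    def test_determinism_given_seed(self, german_like_map):
        rng = np.random.default_rng(9)
        e = german_like_map.populations * 7e-6 * 10
        cases = CaseVector(rng.poisson(e), e)
        r1 = sss_detect(german_like_map, cases, n_mc=99, rng=7)
        r2 = sss_detect(german_like_map, cases, n_mc=99, rng=7)
        assert r1.p_value == r2.p_value
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_population_scaling_invariance(self):
        dmap = square_lattice(4, populations=100.0)
        rng = np.random.default_rng(10)
        c = rng.poisson(2.0, 16)
        c[0] += 10
        r1 = ScanStatistic(dmap, CaseVector(c, np.full(16, 2.0)), max_frac=0.5,
                           n_mc=9, seed=0).fit()
        scaled = DistrictMap(dmap.district_ids, dmap.adjacency,
                             dmap.populations * 13.0, dmap.centroids)
        r2 = ScanStatistic(scaled, CaseVector(c, np.full(16, 2.0)), max_frac=0.5,
                           n_mc=9, seed=0).fit()
        assert r1.llr_max == pytest.approx(r2.llr_max, rel=1e-12)

    def test_adding_case_to_ml_zone_cannot_decrease_llr(self):
        dmap = square_lattice(4, populations=100.0)
        rng = np.random.default_rng(11)
        for _ in range(10):
            c = rng.poisson(2.0, 16)
            c[5] += 8
            cases = CaseVector(c, np.full(16, 2.0))
            res = ScanStatistic(dmap, cases, max_frac=0.5, n_mc=9, seed=0).fit()
            if res.most_likely is None:
                continue
            c2 = c.copy()
            c2[res.most_likely.members[0]] += 1
            res2 = ScanStatistic(dmap, CaseVector(c2, cases.expected), max_frac=0.5,
                                 n_mc=9, seed=0).fit()
            assert res2.llr_max >= res.llr_max - 1e-12

    def test_null_pvalues_uniform(self):
        """Monte Carlo p under the null is (discretely) uniform: KS at alpha=0.01."""
        dmap = square_lattice(5, populations=1000.0)
        e = np.full(25, 4.0)
        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(500):
            cases = CaseVector(rng.poisson(e), e)
            if cases.C == 0:
                continue
            res = ScanStatistic(dmap, cases, max_frac=0.3, n_mc=199,
                                seed=rng).fit()
            pvals.append(res.p_value)
        from scipy import stats

        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_secondary_clusters_cover_split_risk(self):
        """Two far-apart hot spots: secondaries catch the second one."""
        dmap = square_lattice(6, populations=100.0)
        c = np.full(36, 1, dtype=int)
        c[0] += 25   # corner (0,0)
        c[35] += 25  # opposite corner (5,5)
        cases = CaseVector(c, np.full(36, 1.5))
        res = ScanStatistic(dmap, cases, max_frac=0.2, n_mc=199, seed=0,
                            include_secondary=True).fit()
        strict = ScanStatistic(dmap, cases, max_frac=0.2, n_mc=199, seed=0,
                               include_secondary=False).fit()
        assert res.labels[0] and res.labels[35]
        assert strict.labels.sum() <= res.labels.sum()
        assert not (strict.labels[0] and strict.labels[35])
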