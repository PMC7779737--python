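import math

import numpy as np
import pytest

from clusterbench import (
    BesagNewell,
    CaseVector,
    LatticeSpec,
    bn_detect,
    bn_neighbor_order,
    bn_pvalue,
    make_lattice_map,
)
from clusterbench.geography import DistrictMap
from conftest import square_lattice


def poisson_tail_oracle(k: int, mu: float) -> float:
    """p = 1 - sum_{s=0}^{k-1} exp(-mu) mu^s / s! by direct summation."""
    acc = 0.0
    term = math.exp(-mu)
    for s in range(k):
        acc += term
        term *= mu / (s + 1)
    return 1.0 - acc


@pytest.fixture
def path3():
    return make_lattice_map(
        LatticeSpec(rows=1, cols=3, log_mean=0.0, log_sd=0.5, min_pop=1, max_pop=9, seed=0)
    )


@pytest.fixture
def pair_map():
    """Two districts with populations 10 and 90 (N=100)."""
    return DistrictMap(
        ["A", "B"], [[0, 1], [1, 0]], [10.0, 90.0], [(0, 0), (1, 0)]
    )


class TestNeighborOrder:
    def test_collinear(self, path3):
        order = bn_neighbor_order(path3)
        assert order[0].tolist() == [1, 2]
        assert order[2].tolist() == [1, 0]

    def test_equidistant_tie_lower_id_first(self):
        dmap = DistrictMap(
            ["A", "B", "C"], np.zeros((3, 3), int) ^ np.array([[0,1,1],[1,0,0],[1,0,0]]),
            np.ones(3), [(0.0, 0.0), (1.0, 0.0), (-1.0, 0.0)],
        )
        order = bn_neighbor_order(dmap)
        assert order[0].tolist() == [1, 2]

    def test_matches_brute_force_sort(self, german_like_map):
        order = bn_neighbor_order(german_like_map)
        D = german_like_map.distance_matrix()
        for i in (0, 57, 200, 401):
            oracle = sorted(
                (j for j in range(german_like_map.H) if j != i),
                key=lambda j: (D[i, j], j),
            )
            assert order[i].tolist() == oracle


class TestBNPvalue:
    def test_closed_form_k1(self, pair_map):
        # c = [1, 9]: m=0 at district A, mu = 10 * 10 / 100 = 1
        cv = CaseVector(np.array([1, 9]), np.array([1.0, 9.0]))
        order = bn_neighbor_order(pair_map)
        m, p = bn_pvalue(0, 1, cv, pair_map, order)
        assert m == 0
        assert p == pytest.approx(1 - math.exp(-1), abs=1e-12)

    def test_closed_form_k5(self, pair_map):
        cv = CaseVector(np.array([5, 5]), np.array([1.0, 9.0]))
        order = bn_neighbor_order(pair_map)
        m, p = bn_pvalue(0, 5, cv, pair_map, order)
        assert m == 0
        expected = 1 - math.exp(-1) * (1 + 1 + 0.5 + 1 / 6 + 1 / 24)
        assert p == pytest.approx(expected, abs=1e-12)
        assert p == pytest.approx(0.00366, abs=5e-6)

    def test_k1_zero_neighbors(self, path3):
        cv = CaseVector(np.array([1, 0, 0]), np.ones(3))
        m, _ = bn_pvalue(0, 1, cv, path3, bn_neighbor_order(path3))
        assert m == 0

    def test_never_reached_flagged(self, path3):
        cv = CaseVector(np.array([1, 0, 0]), np.ones(3))
        m, p = bn_pvalue(0, 50, cv, path3, bn_neighbor_order(path3))
        assert (m, p) == (path3.H - 1, 1.0)

    def test_plus_one_dialect_stops_earlier(self, path3):
        cv = CaseVector(np.array([1, 1, 1]), np.ones(3))
        order = bn_neighbor_order(path3)
        m_std, _ = bn_pvalue(0, 2, cv, path3, order)
        m_plus, _ = bn_pvalue(0, 2, cv, path3, order, plus_one=True)
        assert m_std == 1 and m_plus == 0

    def test_moving_case_into_circle_cannot_increase_p(self, german_like_map):
        """At fixed C, concentrating cases at the center shrinks the circle
        (and its population share), so the tail probability cannot rise."""
        rng = np.random.default_rng(4)
        e = german_like_map.populations * 7e-6 * 10
        order = bn_neighbor_order(german_like_map)
        for _ in range(20):
            c = rng.poisson(e)
            if c.sum() < 6:
                continue
            cv = CaseVector(c, e)
            i = int(rng.integers(german_like_map.H))
            _, p0 = bn_pvalue(i, 5, cv, german_like_map, order)
            donors = np.flatnonzero(c)
            donors = donors[donors != i]
            if donors.size == 0:
                continue
            c2 = c.copy()
            c2[donors[-1]] -= 1
            c2[i] += 1
            _, p1 = bn_pvalue(i, 5, CaseVector(c2, e), german_like_map, order)
            assert p1 <= p0 + 1e-12


class TestBNDetect:
    def test_no_cases_no_detection(self, german_like_map):
        e = german_like_map.populations * 7e-6 * 10
        cv = CaseVector(np.zeros(german_like_map.H, dtype=int), e)
        res = bn_detect(german_like_map, cv, k=5)
        assert res.R == 0
        assert not res.labels.any()

    def test_concentrated_cases_detected(self):
        dmap = square_lattice(10, populations=1000.0)
        c = np.zeros(100, dtype=int)
        c[55] = 50
        cv = CaseVector(c, np.full(100, 0.5))
        res = bn_detect(dmap, cv, k=5)
        # circle = the district itself: mu = U*C/N = 0.5, P(Pois >= 5) tiny
        assert res.p_values[55] < 0.05
        assert res.labels[55]

    def test_k_beyond_total_cases(self, german_like_map):
        rng = np.random.default_rng(5)
        e = german_like_map.populations * 7e-6 * 10
        cv = CaseVector(rng.poisson(e), e)
        res = bn_detect(german_like_map, cv, k=cv.C + 1)
        assert res.R == 0

    def test_fit_matches_bn_pvalue(self, german_like_map):
        rng = np.random.default_rng(6)
        e = german_like_map.populations * 7e-6 * 10
        cv = CaseVector(rng.poisson(e), e)
        order = bn_neighbor_order(german_like_map)
        res = BesagNewell(german_like_map, cv, k=5).fit()
        for i in (0, 17, 100, 399):
            m, p = bn_pvalue(i, 5, cv, german_like_map, order)
            assert res.m_obs[i] == m
            assert res.p_values[i] == pytest.approx(p, abs=1e-14)

    def test_labels_are_union_of_significant_circles(self, german_like_map):
        rng = np.random.default_rng(7)
        e = german_like_map.populations * 7e-6 * 10
        c = rng.poisson(e)
        c[40] += 20  # force one strong circle
        res = bn_detect(german_like_map, CaseVector(c, e), k=5)
        union = set()
        for i in np.flatnonzero(res.significant):
            union |= set(res.circle_members(i).tolist())
        assert set(np.flatnonzero(res.labels).tolist()) == union

    def test_center_only_labeling(self, german_like_map):
        rng = np.random.default_rng(7)
        e = german_like_map.populations * 7e-6 * 10
        c = rng.poisson(e)
        c[40] += 20
        cv = CaseVector(c, e)
        res = bn_detect(german_like_map, cv, k=5, label_center_only=True)
        np.testing.assert_array_equal(res.labels, res.significant)

    def test_permutation_equivariance_of_R(self, german_like_map):
        # jitter centroids so distance rankings are tie-free, hence
        # independent of the (id-based) tie-break under relabeling
        rng = np.random.default_rng(8)
        jitter = rng.normal(scale=1e-4, size=german_like_map.centroids.shape)
        base = DistrictMap(
            german_like_map.district_ids,
            german_like_map.adjacency,
            german_like_map.populations,
            german_like_map.centroids + jitter,
        )
        e = base.populations * 7e-6 * 10
        cv = CaseVector(rng.poisson(e), e)
        res = bn_detect(base, cv, k=5)

        perm = rng.permutation(base.H)
        pmap = DistrictMap(
            [base.district_ids[i] for i in perm],
            base.adjacency[np.ix_(perm, perm)],
            base.populations[perm],
            base.centroids[perm],
        )
        pres = bn_detect(pmap, CaseVector(cv.cases[perm], cv.expected[perm]), k=5)
        assert pres.R == res.R
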