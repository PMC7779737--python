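"""Shared fixtures: small hand-checkable maps and the benchmark lattices."""

from __future__ import annotations

import numpy as np
import pytest

from clusterbench import (
    CaseVector,
    DistrictMap,
    LatticeSpec,
    german_like_spec,
    make_lattice_map,
)


def square_lattice(n: int, populations: np.ndarray | float = 1.0) -> DistrictMap:
    """n x n rook lattice with constant or given populations."""
    spec = LatticeSpec(rows=n, cols=n, log_mean=0.0, log_sd=0.5, min_pop=1, max_pop=9, seed=0)
    dmap = make_lattice_map(spec)
    pops = np.full(n * n, float(populations)) if np.isscalar(populations) else populations
    return DistrictMap(dmap.district_ids, dmap.adjacency, pops, dmap.centroids)


@pytest.fixture
def two_district_map() -> DistrictMap:
    return DistrictMap(
        ["A", "B"],
        np.array([[0, 1], [1, 0]]),
        np.array([10.0, 20.0]),
        np.array([[0.0, 0.0], [1.0, 0.0]]),
    )


@pytest.fixture
def lattice3() -> DistrictMap:
    """3x3 rook lattice, unit populations."""
    return square_lattice(3)


@pytest.fixture
def lattice5() -> DistrictMap:
    return square_lattice(5)


@pytest.fixture(scope="session")
def german_like_map() -> DistrictMap:
    """402-cell lattice with German-scale truncated log-normal populations."""
    return make_lattice_map(german_like_spec(seed=0))


@pytest.fixture(scope="session")
def uniform402_map() -> DistrictMap:
    """402-cell lattice with uniform populations of 100,000 (e_i = 7 over 10y)."""
    base = make_lattice_map(german_like_spec(seed=0))
    return DistrictMap(
        base.district_ids,
        base.adjacency,
        np.full(base.H, 100_000.0),
        base.centroids,
    )


def cases_from_counts(counts, dmap: DistrictMap, rate=7e-6, years=10) -> CaseVector:
    return CaseVector(np.asarray(counts), rate * dmap.populations * years)
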