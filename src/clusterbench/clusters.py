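"""Random generation of connected high-risk district clusters.

A true cluster is grown from a uniformly random starting district by
repeatedly adding a uniformly random district from the frontier (non-members
adjacent to the current member set) until the target size is reached.  If
the grown set encloses a "donut hole" — a district all of whose neighbors
are members — the hole is filled, so the final cluster may exceed the target
size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .geography import DistrictMap

__all__ = ["TrueCluster", "grow_cluster", "fill_enclosures", "ClusterGrowthError"]


class ClusterGrowthError(RuntimeError):
    """Cluster growth could not reach the target size."""


@dataclass(frozen=True)
class TrueCluster:
    """A connected set of high-risk districts and its relative risk.

    ``member_districts`` holds district indices into the map; its size is at
    least ``target_size`` (strictly greater only when donut filling added
    enclosed districts).  ``rr`` multiplies the baseline incidence inside the
    cluster; outside, the relative risk is 1.
    """

    member_districts: frozenset[int]
    target_size: int
    rr: float = 1.0
    start: int | None = None

    @property
    def size(self) -> int:
        return len(self.member_districts)

    def indicator(self, H: int) -> np.ndarray:
        mask = np.zeros(H, dtype=bool)
        mask[list(self.member_districts)] = True
        return mask

    def with_rr(self, rr: float) -> "TrueCluster":
        return TrueCluster(self.member_districts, self.target_size, rr, self.start)

    def to_json(self, dmap: DistrictMap, seed: int | None = None) -> str:
        return json.dumps(
            {
                "seed": seed,
                "size": self.target_size,
                "rr": self.rr,
                "member_ids": sorted(dmap.district_ids[i] for i in self.member_districts),
            }
        )


def fill_enclosures(dmap: DistrictMap, members: frozenset[int] | set[int]) -> frozenset[int]:
    """Add every district all of whose neighbors lie inside ``members``.

    Repeated to a fixed point, so nested enclosures (rings within rings) are
    filled completely.  Idempotent.
    """
    current = set(members)
    changed = True
    while changed:
        changed = False
        for i in range(dmap.H):
            if i in current:
                continue
            nb = dmap.neighbors_of(i)
            if len(nb) and all(j in current for j in nb):
                current.add(i)
                changed = True
    return frozenset(current)


def grow_cluster(
    dmap: DistrictMap,
    size: int,
    rng: np.random.Generator,
    rr: float = 1.0,
    max_retries: int = 100,
    fill_donuts: bool = True,
) -> TrueCluster:
    """Grow a connected cluster of ``size`` adjacent districts.

    The starting district is uniform over all districts; each growth step
    picks uniformly among the frontier (non-member districts adjacent to the
    member set).  If growth stalls inside a component smaller than ``size``,
    a fresh start is drawn, up to ``max_retries`` times.
    """
    if not 1 <= size <= dmap.H:
        raise ValueError(f"cluster size {size} outside [1, {dmap.H}]")

    W = dmap.adjacency
    for _ in range(max_retries):
        start = int(rng.integers(dmap.H))
        members = [start]
        mask = np.zeros(dmap.H, dtype=bool)
        mask[start] = True
        frontier_mask = W[start].astype(bool) & ~mask
        while len(members) < size:
            frontier = np.flatnonzero(frontier_mask)
            if frontier.size == 0:
                break  # stuck in a small component; restart
            nxt = int(frontier[rng.integers(frontier.size)])
            members.append(nxt)
            mask[nxt] = True
            frontier_mask |= W[nxt].astype(bool)
            frontier_mask &= ~mask
        if len(members) == size:
            final = frozenset(members)
            if fill_donuts:
                final = fill_enclosures(dmap, final)
            return TrueCluster(final, target_size=size, rr=rr, start=start)

    raise ClusterGrowthError(
        f"could not grow a connected cluster of size {size} in {max_retries} attempts"
    )
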