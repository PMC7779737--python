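"""Synthetic lattice geographies with German-district-like population structure.

The real study region is the system of 402 German NUTS-3 districts with
under-15 populations between 3,594 and 492,448 summing to about 11.05
million children.  For testing every downstream stage without downloads,
this module builds rook-adjacency lattices whose cell populations are drawn
from a truncated log-normal calibrated to that range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geography import DistrictMap

__all__ = ["LatticeSpec", "make_lattice_map", "german_like_spec"]

# Bounds of the under-15 district populations in the German system.
GERMAN_MIN_POP = 3_594
GERMAN_MAX_POP = 492_448
GERMAN_TOTAL_POP = 11_048_523
GERMAN_N_DISTRICTS = 402


@dataclass
class LatticeSpec:
    """Recipe for a rook-adjacency lattice map.

    ``n_districts`` trims the lattice to a non-rectangular count by removing
    cells from the end of the last row (connectivity is preserved because
    every remaining cell keeps its neighbor in the row above).  Populations
    are i.i.d. truncated log-normal: ``log_mean``/``log_sd`` parameterize the
    underlying normal, ``min_pop``/``max_pop`` the truncation interval.
    """

    rows: int = 21
    cols: int = 20
    n_districts: int | None = None
    log_mean: float = float(np.log(20_000.0))
    log_sd: float = 1.0
    min_pop: float = GERMAN_MIN_POP
    max_pop: float = GERMAN_MAX_POP
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows * self.cols < 2:
            raise ValueError("lattice must contain at least 2 cells")
        if self.min_pop < 1 or self.max_pop < self.min_pop:
            raise ValueError("population bounds must satisfy 1 <= min <= max")
        if self.n_districts is not None:
            if not (2 <= self.n_districts <= self.rows * self.cols):
                raise ValueError("n_districts out of range for the lattice")
            if self.n_districts <= (self.rows - 1) * self.cols:
                raise ValueError(
                    "trimming may only shorten the last row; reduce `rows` instead"
                )


def german_like_spec(seed: int = 0) -> LatticeSpec:
    """A 402-cell lattice emulating the German district system's scale."""
    return LatticeSpec(rows=21, cols=20, n_districts=GERMAN_N_DISTRICTS, seed=seed)


def _truncated_lognormal(
    rng: np.random.Generator, n: int, log_mean: float, log_sd: float,
    lo: float, hi: float,
) -> np.ndarray:
    """Rejection-sample n truncated log-normal variates."""
    out = np.empty(n)
    filled = 0
    drawn = accepted = 0
    while filled < n:
        draw = rng.lognormal(log_mean, log_sd, size=max(2 * (n - filled), 64))
        keep = draw[(draw >= lo) & (draw <= hi)]
        drawn += draw.size
        accepted += keep.size
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
        if drawn > 10_000 * max(n, 1) and accepted == 0:
            raise ValueError(
                f"truncation interval [{lo}, {hi}] has negligible mass under "
                f"lognormal(log_mean={log_mean:.3g}, log_sd={log_sd:.3g})"
            )
    return out


def make_lattice_map(spec: LatticeSpec) -> DistrictMap:
    """Build a rook-adjacency lattice DistrictMap from a LatticeSpec.

    Deterministic given ``spec.seed``: the same spec always yields the same
    map.  Centroids sit at integer grid coordinates (col, -row) so that
    Euclidean distance matches grid distance.
    """
    rows, cols = spec.rows, spec.cols
    n = spec.n_districts if spec.n_districts is not None else rows * cols
    # cell (r, c) -> flat index r*cols + c; keep the first n cells
    coords = [(i // cols, i % cols) for i in range(n)]
    index = {rc: i for i, rc in enumerate(coords)}

    W = np.zeros((n, n), dtype=np.int8)
    for (r, c), i in index.items():
        for dr, dc in ((0, 1), (1, 0)):
            j = index.get((r + dr, c + dc))
            if j is not None:
                W[i, j] = W[j, i] = 1

    rng = np.random.default_rng(spec.seed)
    pops = np.round(
        _truncated_lognormal(rng, n, spec.log_mean, spec.log_sd, spec.min_pop, spec.max_pop)
    )
    ids = [f"D{i:03d}" for i in range(n)]
    centroids = np.array([(c, -r) for r, c in coords], dtype=float)
    return DistrictMap(ids, W, pops, centroids)
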