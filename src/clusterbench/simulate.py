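"""Poisson simulation of 10-year aggregated case counts per district.

Under the null every district sees cases at the baseline annual incidence
``rate`` (nephroblastoma 7 per million children, all childhood malignancies
140 per million); inside a designated high-risk cluster the rate is
multiplied by the cluster's relative risk.  Counts are aggregated over a
``years``-long window (default 10) with the population held at a single
snapshot, so the expected count is ``e_i = rate * u_i * years`` and the
simulated count is one Poisson draw with mean ``RR_i * e_i`` (a single draw
with the summed mean is distributionally identical to summing annual draws).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clusters import TrueCluster
from .geography import DistrictMap

__all__ = [
    "ScenarioConfig",
    "CaseVector",
    "expected_cases",
    "simulate_cases",
    "crude_rate",
    "cumulative_rr",
    "NEPHROBLASTOMA_RATE",
    "ALL_MALIGNANCIES_RATE",
    "DEFAULT_RR_LEVELS",
    "DEFAULT_CLUSTER_SIZES",
]

NEPHROBLASTOMA_RATE = 7e-6
ALL_MALIGNANCIES_RATE = 140e-6
DEFAULT_RR_LEVELS = (1.0, 1.1, 1.2, 1.3, 1.4, 1.5, 2.0, 5.0, 10.0, 100.0)
DEFAULT_CLUSTER_SIZES = (1, 2, 3, 5, 10, 20, 50)


@dataclass
class ScenarioConfig:
    """Simulation scenario: baseline rate, aggregation window and grids."""

    baseline_rate: float = NEPHROBLASTOMA_RATE
    years: int = 10
    rr_levels: tuple[float, ...] = DEFAULT_RR_LEVELS
    cluster_sizes: tuple[int, ...] = DEFAULT_CLUSTER_SIZES
    iterations: int = 2000
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.years < 1 or self.iterations < 1:
            raise ValueError("years and iterations must be >= 1")
        if any(r < 0 for r in self.rr_levels):
            raise ValueError("relative risks must be nonnegative")


@dataclass
class CaseVector:
    """Simulated aggregated counts c_i with the expected counts e_i they are scored against."""

    cases: np.ndarray
    expected: np.ndarray

    def __post_init__(self) -> None:
        self.cases = np.asarray(self.cases)
        self.expected = np.asarray(self.expected, dtype=float)
        if self.cases.shape != self.expected.shape:
            raise ValueError("cases and expected must align")
        if np.any(self.cases < 0):
            raise ValueError("case counts must be nonnegative")
        if np.any(self.expected <= 0):
            raise ValueError("expected counts must be positive")

    @property
    def C(self) -> int:
        """Total number of cases."""
        return int(self.cases.sum())

    def to_frame(self, dmap: DistrictMap) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "district_id": dmap.district_ids,
                "cases": self.cases,
                "expected": self.expected,
            }
        )


def expected_cases(dmap: DistrictMap, rate: float, years: int = 10) -> np.ndarray:
    """Baseline expected counts e_i = rate * u_i * years."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    if years < 1:
        raise ValueError("years must be >= 1")
    return rate * dmap.populations * years


def simulate_cases(
    dmap: DistrictMap,
    cluster: TrueCluster | None,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> CaseVector:
    """Draw c_i ~ Poisson(RR_i * e_i) with RR_i elevated inside the cluster."""
    e = expected_cases(dmap, config.baseline_rate, config.years)
    rr = np.ones(dmap.H)
    if cluster is not None:
        members = list(cluster.member_districts)
        if members and (min(members) < 0 or max(members) >= dmap.H):
            raise ValueError("cluster members are not districts of this map")
        rr[members] = cluster.rr
    c = rng.poisson(rr * e)
    return CaseVector(cases=c, expected=e)


def crude_rate(cases: CaseVector, dmap: DistrictMap, years: int = 10) -> np.ndarray:
    """Crude annual incidence per million: c_i / (u_i * years) * 1e6."""
    return cases.cases / (dmap.populations * years) * 1e6


def cumulative_rr(cases: CaseVector) -> np.ndarray:
    """District cumulative relative-risk estimand over the window: c_i / e_i."""
    return cases.cases / cases.expected
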