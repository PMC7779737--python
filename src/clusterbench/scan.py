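"""Kulldorff circular spatial scan statistic (Poisson model, conditional).

Candidate zones are nested circles: for every center district, districts are
added in order of centroid distance while the zone population stays below a
fraction ``max_frac`` of the total (the study caps it at 10%).  For a zone
with ``D`` of the ``C`` total cases and population share ``U/N`` the
log-likelihood ratio against the constant-risk null is

    LLR = D log(D/E) + (C - D) log((C - D)/(C - E)),   E = U C / N,

taken only when ``D > E`` (zero otherwise).  The test statistic ``T`` is the
maximum LLR over all zones; significance is Monte Carlo, redistributing the
``C`` cases multinomially with probabilities ``u_i / N`` and recomputing the
maximum, with ``p = (1 + #{T* >= T}) / (1 + n_mc)``.

Secondary clusters follow the SaTScan convention: zones disjoint from every
already-reported cluster whose own LLR exceeds the ``(1 - alpha)`` quantile
of the replicate maxima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import xlogy

from .besag_newell import bn_neighbor_order
from .geography import DistrictMap
from .simulate import CaseVector

__all__ = ["ScanStatistic", "ScanResults", "Zone", "sss_zones", "sss_llr", "sss_detect"]


@dataclass(frozen=True)
class Zone:
    """A circular candidate zone: a center plus its nearest districts."""

    center: int
    members: tuple[int, ...]  # ordered by distance from center, center first
    U: float  # zone population
    D: int = 0  # zone case count (filled when scored)
    llr: float = 0.0

    def __len__(self) -> int:
        return len(self.members)


def sss_llr(D: float, U: float, C: float, N: float) -> float:
    """Poisson scan log-likelihood ratio for one zone; 0 unless D > E."""
    if not 0 <= D <= C:
        raise ValueError("need 0 <= D <= C")
    if not 0 < U < N:
        raise ValueError("need 0 < U < N")
    E = U * C / N
    if D <= E:
        return 0.0
    return float(xlogy(D, D / E) + xlogy(C - D, (C - D) / (C - E)))


def sss_zones(dmap: DistrictMap, max_frac: float = 0.1) -> list[Zone]:
    """Enumerate all distinct population-capped circular zones."""
    if not 0 < max_frac <= 1:
        raise ValueError("max_frac must be in (0, 1]")
    order = bn_neighbor_order(dmap)
    u = dmap.populations
    cap = max_frac * dmap.N
    zones: list[Zone] = []
    seen: set[tuple[int, ...]] = set()
    for i in range(dmap.H):
        members = [i]
        U = u[i]
        if U > cap:
            continue
        key = (i,)
        if key not in seen:
            seen.add(key)
            zones.append(Zone(i, key, U))
        for j in order[i]:
            if U + u[j] > cap:
                break
            members.append(int(j))
            U += u[j]
            key = tuple(sorted(members))
            if key not in seen:
                seen.add(key)
                zones.append(Zone(i, tuple(members), U))
    return zones


@njit(cache=True)
def _max_llr_kernel(cases, order, lengths, EU, C):
    """Maximum zone LLR for each replicate case vector.

    cases: (R, H) int64 replicate counts; order: (H, Lmax) ranked neighbor
    indices; lengths: zone length per center (0 = center over cap);
    EU: (H, Lmax+1) expected counts E for prefix sizes 1..len.
    """
    R, H = cases.shape
    out = np.zeros(R)
    for r in range(R):
        best = 0.0
        c = cases[r]
        for i in range(H):
            L = lengths[i]
            if L == 0:
                continue
            d = float(c[i])
            for j in range(L):
                if j > 0:
                    d += c[order[i, j - 1]]
                e = EU[i, j]
                if d > e:
                    rem = C - d
                    llr = d * np.log(d / e)
                    if rem > 0.0:
                        llr += rem * np.log(rem / (C - e))
                    if llr > best:
                        best = llr
        out[r] = best
    return out


class ScanStatistic:
    """Circular spatial scan over a map and one case vector.

    Parameters
    ----------
    max_frac
        Maximum zone population as a fraction of total population (0.1 in
        the benchmark).
    n_mc
        Monte Carlo replicates for the null distribution of the maximum.
    include_secondary
        Also report (and label) non-overlapping zones whose LLR exceeds the
        replicate critical value — required to cover true clusters larger
        than the population cap allows a single circle to be.
    """

    def __init__(
        self,
        dmap: DistrictMap,
        cases: CaseVector,
        max_frac: float = 0.1,
        n_mc: int = 999,
        alpha: float = 0.05,
        include_secondary: bool = True,
        seed: int | np.random.Generator = 0,
    ) -> None:
        if n_mc < 1:
            raise ValueError("n_mc must be >= 1")
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.dmap = dmap
        self.cases = cases
        self.max_frac = max_frac
        self.n_mc = n_mc
        self.alpha = alpha
        self.include_secondary = include_secondary
        self.rng = (
            seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        )
        self._geom = None  # cached (order, lengths, EU-ready cumU)

    # -- zone geometry, shared across fits on the same map ----------------
    def _geometry(self):
        if self._geom is None:
            self._geom = _scan_geometry(self.dmap, self.max_frac)
        return self._geom

    def fit(self) -> "ScanResults":
        dmap, cases = self.dmap, self.cases
        C = cases.C
        order, lengths, cumU = self._geometry()
        H = dmap.H
        if C == 0:
            return ScanResults(
                self, most_likely=None, llr_max=0.0, p_value=1.0,
                secondary=[], labels=np.zeros(H, dtype=bool), critical_value=np.inf,
                null_max=np.array([]),
            )
        EU = cumU * (C / dmap.N)

        # observed scan: best zone per center (max over these is T)
        zone_best = _per_center_zones(cases.cases, order, lengths, cumU, EU, float(C))

        # Monte Carlo null: multinomial redistribution of C cases
        probs = dmap.populations / dmap.N
        null_max = np.empty(self.n_mc)
        chunk = max(1, min(self.n_mc, 250))
        done = 0
        while done < self.n_mc:
            b = min(chunk, self.n_mc - done)
            reps = self.rng.multinomial(C, probs, size=b).astype(np.int64)
            null_max[done : done + b] = _max_llr_kernel(
                reps, order, lengths, EU, float(C)
            )
            done += b

        llr_max = max((z.llr for z in zone_best), default=0.0)
        p_value = float((1 + np.sum(null_max >= llr_max)) / (1 + self.n_mc))
        critical = float(np.quantile(null_max, 1 - self.alpha))

        # most likely cluster and (optionally) secondary clusters
        ranked = sorted(zone_best, key=lambda z: -z.llr)
        most_likely = ranked[0] if ranked and ranked[0].llr > 0 else None
        labels = np.zeros(H, dtype=bool)
        secondary: list[Zone] = []
        if most_likely is not None and p_value < self.alpha:
            labels[list(most_likely.members)] = True
            if self.include_secondary:
                taken = set(most_likely.members)
                for z in ranked[1:]:
                    if z.llr <= critical:
                        break
                    if taken.isdisjoint(z.members):
                        secondary.append(z)
                        taken |= set(z.members)
                        labels[list(z.members)] = True
        return ScanResults(
            self, most_likely, llr_max, p_value, secondary, labels, critical, null_max
        )


def _scan_geometry(dmap: DistrictMap, max_frac: float):
    """Ranked neighbor matrix, capped zone lengths, and cumulative populations."""
    if not 0 < max_frac <= 1:
        raise ValueError("max_frac must be in (0, 1]")
    order = bn_neighbor_order(dmap)
    u = dmap.populations
    cap = max_frac * dmap.N
    H = dmap.H
    cum = u[:, None] + np.concatenate(
        [np.zeros((H, 1)), np.cumsum(u[order], axis=1)], axis=1
    )  # (H, H): population of the prefix zone of size j+1
    lengths = np.array(
        [int(np.searchsorted(cum[i], cap, side="right")) for i in range(H)],
        dtype=np.int64,
    )
    Lmax = max(1, int(lengths.max()))
    return order[:, : max(0, Lmax - 1)], lengths, cum[:, :Lmax]


def _per_center_zones(cases, order, lengths, cumU, EU, C) -> list[Zone]:
    """Best zone per center on the observed counts (python-side, for reporting)."""
    H = len(lengths)
    zones: list[Zone] = []
    for i in range(H):
        L = lengths[i]
        if L == 0:
            continue
        members = np.concatenate(([i], order[i, : L - 1]))
        D_cum = np.cumsum(cases[members]).astype(float)
        E = EU[i, :L]
        with np.errstate(divide="ignore", invalid="ignore"):
            rem = C - D_cum
            llr = np.where(
                D_cum > E,
                xlogy(D_cum, D_cum / E) + xlogy(rem, rem / (C - E)),
                0.0,
            )
        j = int(np.argmax(llr))
        zones.append(
            Zone(
                center=i,
                members=tuple(int(m) for m in members[: j + 1]),
                U=float(cumU[i, j]),
                D=int(D_cum[j]),
                llr=float(llr[j]),
            )
        )
    return zones


@dataclass
class ScanResults:
    """Most likely cluster, Monte Carlo p-value and high-risk labels."""

    model: ScanStatistic
    most_likely: Zone | None
    llr_max: float
    p_value: float
    secondary: list[Zone]
    labels: np.ndarray
    critical_value: float
    null_max: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        dmap = self.model.dmap
        zone_id = np.full(dmap.H, -1)
        if self.most_likely is not None and self.p_value < self.model.alpha:
            zone_id[list(self.most_likely.members)] = 0
            for k, z in enumerate(self.secondary, start=1):
                zone_id[list(z.members)] = k
        return pd.DataFrame(
            {
                "district_id": dmap.district_ids,
                "labeled": self.labels.astype(int),
                "zone_id": zone_id,
            }
        )

    def metadata(self) -> dict:
        return {
            "llr_max": self.llr_max,
            "p_value": self.p_value,
            "critical_value": self.critical_value,
            "n_mc": self.model.n_mc,
            "max_frac": self.model.max_frac,
            "include_secondary": self.model.include_secondary,
            "most_likely": None
            if self.most_likely is None
            else [self.model.dmap.district_ids[i] for i in self.most_likely.members],
            "n_secondary": len(self.secondary),
        }

    def summary(self) -> str:
        lines = [
            "Kulldorff spatial scan statistic (Poisson, conditional)",
            f"  districts: {self.model.dmap.H}   total cases: {self.model.cases.C}",
            f"  population cap: {self.model.max_frac:.0%} of N   "
            f"n_mc = {self.model.n_mc}",
            f"  max LLR = {self.llr_max:.4f}   p = {self.p_value:.4f}",
        ]
        if self.most_likely is not None:
            ids = [self.model.dmap.district_ids[i] for i in self.most_likely.members]
            lines.append(f"  most likely cluster ({len(ids)} districts): {ids[:8]}"
                         + (" ..." if len(ids) > 8 else ""))
        lines.append(f"  secondary clusters: {len(self.secondary)}   "
                     f"labeled districts: {int(self.labels.sum())}")
        return "\n".join(lines)


def sss_detect(
    dmap: DistrictMap,
    cases: CaseVector,
    max_frac: float = 0.1,
    n_mc: int = 999,
    alpha: float = 0.05,
    rng: int | np.random.Generator = 0,
    include_secondary: bool = True,
) -> ScanResults:
    """Run the circular scan with Monte Carlo significance; wrapper over the class."""
    return ScanStatistic(
        dmap, cases, max_frac=max_frac, n_mc=n_mc, alpha=alpha,
        include_secondary=include_secondary, seed=rng,
    ).fit()
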