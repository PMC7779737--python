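"""Performance measures for cluster detection, on the percent scale.

For one simulation iteration the detected high-risk labels are compared with
the true cluster as a district-level 2x2 table (TP/FP/FN/TN).  Across
iterations the battery comprises sensitivity, specificity, positive and
negative predictive value, correct classification, minimum power (at least
one true district detected), exact power (exactly the true cluster and
nothing else), positive/negative diagnostic likelihood, false positive and
false negative rates, each with SD and a normal-approximation 95% interval
(mean +/- 1.96 * SE), plus the Monte Carlo error of the cumulative
relative-risk estimand.

Conventions: per-iteration ratios with empty denominators (PPV with no
detected positives, NPV with no negatives) are excluded from their means and
counted; PDL/NDL are formed from the aggregated mean sensitivity and
specificity because their per-iteration versions are usually undefined at
the null; the deposited spreadsheet's "correct proportion (CP)" column has
no published definition and is emitted as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clusters import TrueCluster
from .geography import DistrictMap

__all__ = ["Confusion", "MetricRow", "confusion", "metrics_from_confusions",
           "metrics_table", "PROPORTION_MEASURES"]

PROPORTION_MEASURES = ("sens", "spec", "ppv", "npv", "cc", "ep", "mp", "fpr", "fnr")
Z95 = 1.96


@dataclass(frozen=True)
class Confusion:
    """District-level contingency counts for one iteration."""

    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def H(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    @property
    def truth_size(self) -> int:
        return self.TP + self.FN


def confusion(labels: np.ndarray, truth: TrueCluster, dmap: DistrictMap) -> Confusion:
    """Compare binary high-risk labels with the true cluster on one map."""
    labels = np.asarray(labels, dtype=bool)
    if labels.shape != (dmap.H,):
        raise ValueError("labels do not match the map's districts")
    t = truth.indicator(dmap.H)
    return Confusion(
        TP=int(np.sum(labels & t)),
        FP=int(np.sum(labels & ~t)),
        FN=int(np.sum(~labels & t)),
        TN=int(np.sum(~labels & ~t)),
    )


@dataclass
class MetricRow:
    """All performance measures for one (method, cluster size, RR) cell."""

    method: str
    cluster_size: int
    rr: float
    n_iterations: int
    stats: dict  # measure -> {"mean", "sd", "lci", "uci"}
    mce_rr: float
    n_undefined_ppv: int
    n_undefined_npv: int
    averaging: str = "per_iteration"

    def to_series(self) -> pd.Series:
        out = {
            "method": self.method,
            "cluster_size": self.cluster_size,
            "rr": self.rr,
            "n_iterations": self.n_iterations,
        }
        for m, d in self.stats.items():
            for k in ("mean", "sd", "lci", "uci"):
                out[f"{m}_{k}"] = d[k]
        out["cp_mean"] = np.nan  # no published definition; see module docstring
        out["mce_rr"] = self.mce_rr
        out["n_undefined_ppv"] = self.n_undefined_ppv
        out["n_undefined_npv"] = self.n_undefined_npv
        out["averaging"] = self.averaging
        return pd.Series(out)

    def __getitem__(self, measure: str) -> float:
        return self.stats[measure]["mean"]


def _agg(values: np.ndarray) -> dict:
    """Mean/SD/CI of per-iteration percentages; NaN-safe for empty input."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        return {"mean": np.nan, "sd": np.nan, "lci": np.nan, "uci": np.nan}
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    se = sd / np.sqrt(n)
    return {"mean": mean, "sd": sd, "lci": mean - Z95 * se, "uci": mean + Z95 * se}


def metrics_from_confusions(
    confusions: list[Confusion],
    truth_size: int,
    estimand_samples: np.ndarray | None = None,
    method: str = "",
    cluster_size: int | None = None,
    rr: float = np.nan,
    averaging: str = "per_iteration",
) -> MetricRow:
    """Aggregate one cell's confusions into the full metric battery.

    ``estimand_samples`` holds one cumulative-RR estimand value per
    iteration (its SD across iterations is the Monte Carlo error).
    ``averaging='pooled'`` sums the contingency counts over iterations
    before forming each ratio (binomial SEs on the pooled denominators)
    instead of averaging per-iteration ratios.
    """
    if not confusions:
        raise ValueError("need at least one confusion")
    if truth_size < 1:
        raise ValueError(
            "truth_size must be >= 1: the benchmark always designates a cluster"
        )
    for cf in confusions:
        if cf.truth_size != truth_size:
            raise ValueError("confusion inconsistent with truth_size")
    if averaging not in ("per_iteration", "pooled"):
        raise ValueError("averaging must be 'per_iteration' or 'pooled'")

    n = len(confusions)
    TP = np.array([c.TP for c in confusions], dtype=float)
    FP = np.array([c.FP for c in confusions], dtype=float)
    FN = np.array([c.FN for c in confusions], dtype=float)
    TN = np.array([c.TN for c in confusions], dtype=float)
    H = confusions[0].H

    mp = 100.0 * (TP >= 1)
    ep = 100.0 * ((TP == truth_size) & (FP == 0))
    pos = TP + FP
    neg = TN + FN
    ppv_def = pos > 0
    npv_def = neg > 0

    stats: dict[str, dict] = {}
    if averaging == "per_iteration":
        stats["sens"] = _agg(100.0 * TP / (TP + FN))
        stats["spec"] = _agg(100.0 * TN / (TN + FP))
        stats["cc"] = _agg(100.0 * (TP + TN) / H)
        stats["ppv"] = _agg(100.0 * TP[ppv_def] / pos[ppv_def])
        stats["npv"] = _agg(100.0 * TN[npv_def] / neg[npv_def])
        stats["fpr"] = _agg(100.0 * FP[ppv_def] / pos[ppv_def])
        stats["fnr"] = _agg(100.0 * FN[npv_def] / neg[npv_def])
        stats["mp"] = _agg(mp)
        stats["ep"] = _agg(ep)
    else:  # pooled counts, binomial SEs
        def pooled(num: np.ndarray, den: np.ndarray) -> dict:
            ns, ds = num.sum(), den.sum()
            if ds == 0:
                return {"mean": np.nan, "sd": np.nan, "lci": np.nan, "uci": np.nan}
            p = ns / ds
            se = 100.0 * np.sqrt(p * (1 - p) / ds)
            return {"mean": 100.0 * p, "sd": np.nan,
                    "lci": 100.0 * p - Z95 * se, "uci": 100.0 * p + Z95 * se}

        stats["sens"] = pooled(TP, TP + FN)
        stats["spec"] = pooled(TN, TN + FP)
        stats["cc"] = pooled(TP + TN, TP + FP + FN + TN)
        stats["ppv"] = pooled(TP, pos)
        stats["npv"] = pooled(TN, neg)
        stats["fpr"] = pooled(FP, pos)
        stats["fnr"] = pooled(FN, neg)
        stats["mp"] = _agg(mp)
        stats["ep"] = _agg(ep)

    # diagnostic likelihood ratios from the aggregated means
    mean_sens, mean_spec = stats["sens"]["mean"], stats["spec"]["mean"]
    pdl = mean_sens / (100.0 - mean_spec) if mean_spec < 100.0 else np.inf
    ndl = (100.0 - mean_sens) / mean_spec if mean_spec > 0 else np.inf
    nanstat = {"sd": np.nan, "lci": np.nan, "uci": np.nan}
    stats["pdl"] = {"mean": pdl, **nanstat}
    stats["ndl"] = {"mean": ndl, **nanstat}

    mce = (
        float(np.std(np.asarray(estimand_samples, dtype=float), ddof=1))
        if estimand_samples is not None and len(estimand_samples) > 1
        else np.nan
    )
    return MetricRow(
        method=method,
        cluster_size=cluster_size if cluster_size is not None else truth_size,
        rr=rr,
        n_iterations=n,
        stats=stats,
        mce_rr=mce,
        n_undefined_ppv=int(np.sum(~ppv_def)),
        n_undefined_npv=int(np.sum(~npv_def)),
        averaging=averaging,
    )


def metrics_table(rows: list[MetricRow]) -> pd.DataFrame:
    """Tidy table: one row per method x cluster size x relative risk."""
    return pd.DataFrame([r.to_series() for r in rows]).reset_index(drop=True)
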