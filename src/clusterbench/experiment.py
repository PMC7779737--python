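"""Factorial benchmark: cluster sizes x relative risks x iterations x methods.

For every (cluster size, RR) cell the pipeline draws ``iterations``
independent (true cluster, case vector) pairs, runs each enabled detection
method, scores the labels against the truth, and aggregates one MetricRow
per method.  Seeding is counter-based: every (role, size, rr, iteration)
substream is derived from the master seed with a fixed spawn key, so any
cell — or any single iteration — can be reproduced in isolation and the
cluster stream for a given size is shared across RR levels when
``paired_clusters`` is on (lower-variance RR comparisons).

Cells are checkpointed as CSV files; a resumed run skips finished cells and
re-runs partially written ones.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .besag_newell import BesagNewell
from .bym import BYMModel, BYMSpec
from .clusters import TrueCluster, grow_cluster
from .geography import DistrictMap, read_map_bundle
from .performance import Confusion, MetricRow, confusion, metrics_from_confusions, metrics_table
from .scan import ScanStatistic
from .simulate import CaseVector, ScenarioConfig, cumulative_rr, simulate_cases
from .synthetic import LatticeSpec, make_lattice_map

__all__ = ["ExperimentConfig", "run_experiment", "run_cell", "score_archive"]

log = logging.getLogger("clusterbench")

_DEFAULT_METHODS = {
    "bn": {"enabled": True, "k": 5, "alpha": 0.05, "plus_one": False,
           "label_center_only": False, "population_based_mu": False},
    "sss": {"enabled": True, "max_frac": 0.1, "n_mc": 999, "alpha": 0.05,
            "include_secondary": True},
    "bym": {"enabled": True, "credible_level": 0.95},
}


@dataclass
class ExperimentConfig:
    """Everything needed to run (or resume) the full factorial benchmark."""

    map_bundle: str | None = None
    lattice: LatticeSpec | None = None
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    methods: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_METHODS.items()})
    output_dir: str = "clusterbench_out"
    save_raw: bool = False
    paired_clusters: bool = True

    def __post_init__(self) -> None:
        if self.map_bundle is None and self.lattice is None:
            self.lattice = LatticeSpec()
        merged = {k: dict(v) for k, v in _DEFAULT_METHODS.items()}
        for name, cfg in (self.methods or {}).items():
            if name not in merged:
                raise ValueError(f"unknown method {name!r}")
            merged[name].update(cfg or {})
        self.methods = merged
        if not any(m["enabled"] for m in self.methods.values()):
            raise ValueError("at least one method must be enabled")
        if self.map_bundle is not None and not Path(self.map_bundle).exists():
            raise FileNotFoundError(self.map_bundle)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        map_cfg = raw.get("map", {})
        lattice = None
        if "lattice" in map_cfg:
            lattice = LatticeSpec(**map_cfg["lattice"])
        scen = raw.get("scenario", {})
        for key in ("rr_levels", "cluster_sizes"):
            if key in scen:
                scen[key] = tuple(scen[key])
        out = raw.get("output", {})
        return cls(
            map_bundle=map_cfg.get("bundle"),
            lattice=lattice,
            scenario=ScenarioConfig(**scen),
            methods=raw.get("methods", {}),
            output_dir=out.get("directory", "clusterbench_out"),
            save_raw=bool(out.get("save_raw", False)),
            paired_clusters=bool(raw.get("paired_clusters", True)),
        )

    def load_map(self) -> DistrictMap:
        if self.map_bundle is not None:
            return read_map_bundle(self.map_bundle)
        return make_lattice_map(self.lattice)


# ---------------------------------------------------------------------------
# seeding: fixed spawn-key roles so every substream is addressable

_ROLE_CLUSTER, _ROLE_CASES, _ROLE_METHOD = 0, 1, 2


def _rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


def draw_cell(
    dmap: DistrictMap,
    size: int,
    rr: float,
    it: int,
    scenario: ScenarioConfig,
    paired_clusters: bool = True,
) -> tuple[TrueCluster, CaseVector]:
    """The (cluster, cases) pair for one iteration of one cell."""
    rr_key = 0 if paired_clusters else scenario.rr_levels.index(rr)
    cluster_rng = _rng(scenario.master_seed, _ROLE_CLUSTER, size, rr_key, it)
    cluster = grow_cluster(dmap, size, cluster_rng, rr=rr)
    case_rng = _rng(
        scenario.master_seed, _ROLE_CASES, size, scenario.rr_levels.index(rr), it
    )
    cases = simulate_cases(dmap, cluster, scenario, case_rng)
    return cluster, cases


def _run_methods(
    dmap: DistrictMap,
    cluster: TrueCluster,
    cases: CaseVector,
    methods: dict,
    method_seed_key: tuple[int, ...],
    master_seed: int,
) -> dict[str, np.ndarray | None]:
    labels: dict[str, np.ndarray | None] = {}
    if methods["bn"]["enabled"]:
        try:
            cfg = methods["bn"]
            res = BesagNewell(
                dmap, cases, k=cfg["k"], alpha=cfg["alpha"],
                plus_one=cfg["plus_one"],
                label_center_only=cfg["label_center_only"],
                population_based_mu=cfg["population_based_mu"],
            ).fit()
            labels["bn"] = res.labels
        except Exception:
            log.exception("BN failed")
            labels["bn"] = None
    if methods["sss"]["enabled"]:
        try:
            cfg = methods["sss"]
            res = ScanStatistic(
                dmap, cases, max_frac=cfg["max_frac"], n_mc=cfg["n_mc"],
                alpha=cfg["alpha"], include_secondary=cfg["include_secondary"],
                seed=_rng(master_seed, _ROLE_METHOD, *method_seed_key),
            ).fit()
            labels["sss"] = res.labels
        except Exception:
            log.exception("SSS failed")
            labels["sss"] = None
    if methods["bym"]["enabled"]:
        try:
            cfg = {k: v for k, v in methods["bym"].items() if k != "enabled"}
            spec = BYMSpec(**cfg)
            labels["bym"] = BYMModel(dmap, cases, spec).fit().detect()
        except Exception:
            log.exception("BYM failed")
            labels["bym"] = None
    return labels


def run_cell(
    dmap: DistrictMap,
    size: int,
    rr: float,
    config: ExperimentConfig,
    iterations: int | None = None,
) -> tuple[list[MetricRow], list[dict]]:
    """Run every iteration of one (size, rr) cell; returns rows and raw draws."""
    scen = config.scenario
    n_iter = scen.iterations if iterations is None else iterations
    confs: dict[str, list[Confusion]] = {m: [] for m in config.methods}
    estimands: dict[str, list[float]] = {m: [] for m in config.methods}
    failures: dict[str, int] = {m: 0 for m in config.methods}
    raw: list[dict] = []
    rr_idx = scen.rr_levels.index(rr) if rr in scen.rr_levels else -1

    for it in range(n_iter):
        cluster, cases = draw_cell(dmap, size, rr, it, scen, config.paired_clusters)
        est = float(np.mean(cumulative_rr(cases)[list(cluster.member_districts)]))
        labels = _run_methods(
            dmap, cluster, cases, config.methods,
            (size, max(rr_idx, 0), it), scen.master_seed,
        )
        for m, lab in labels.items():
            if lab is None:
                failures[m] += 1
                continue
            confs[m].append(confusion(lab, cluster, dmap))
            estimands[m].append(est)
        if config.save_raw:
            raw.append(
                {
                    "iteration": it,
                    "member_ids": sorted(
                        dmap.district_ids[i] for i in cluster.member_districts
                    ),
                    "target_size": cluster.target_size,
                    "rr": rr,
                    "cases": cases.cases.tolist(),
                }
            )

    rows: list[MetricRow] = []
    for m, cfl in confs.items():
        if not config.methods[m]["enabled"] or not cfl:
            continue
        truth_size = cfl[0].truth_size
        # donut fill can vary the realized truth size between iterations;
        # score each against its own truth but aggregate on the requested size
        groups: dict[int, list[int]] = {}
        for j, cf in enumerate(cfl):
            groups.setdefault(cf.truth_size, []).append(j)
        if len(groups) == 1:
            row = metrics_from_confusions(
                cfl, truth_size, np.array(estimands[m]), method=m,
                cluster_size=size, rr=rr,
            )
        else:
            row = _metrics_mixed_truth(cfl, np.array(estimands[m]), m, size, rr)
        rows.append(row)
        if failures[m]:
            log.warning("cell size=%s rr=%s: %d failed %s iterations",
                        size, rr, failures[m], m)
    return rows, raw


def _metrics_mixed_truth(
    cfl: list[Confusion], est: np.ndarray, method: str, size: int, rr: float
) -> MetricRow:
    """Aggregate a cell whose realized truth sizes differ (donut fill)."""
    from .performance import _agg  # shared aggregation helper

    TP = np.array([c.TP for c in cfl], dtype=float)
    FP = np.array([c.FP for c in cfl], dtype=float)
    FN = np.array([c.FN for c in cfl], dtype=float)
    TN = np.array([c.TN for c in cfl], dtype=float)
    ts = TP + FN
    H = cfl[0].H
    pos, neg = TP + FP, TN + FN
    pd_, nd_ = pos > 0, neg > 0
    stats = {
        "sens": _agg(100 * TP / ts),
        "spec": _agg(100 * TN / (TN + FP)),
        "cc": _agg(100 * (TP + TN) / H),
        "ppv": _agg(100 * TP[pd_] / pos[pd_]),
        "npv": _agg(100 * TN[nd_] / neg[nd_]),
        "fpr": _agg(100 * FP[pd_] / pos[pd_]),
        "fnr": _agg(100 * FN[nd_] / neg[nd_]),
        "mp": _agg(100.0 * (TP >= 1)),
        "ep": _agg(100.0 * ((TP == ts) & (FP == 0))),
    }
    mean_sens, mean_spec = stats["sens"]["mean"], stats["spec"]["mean"]
    nanstat = {"sd": np.nan, "lci": np.nan, "uci": np.nan}
    stats["pdl"] = {"mean": mean_sens / (100 - mean_spec) if mean_spec < 100 else np.inf,
                    **nanstat}
    stats["ndl"] = {"mean": (100 - mean_sens) / mean_spec if mean_spec > 0 else np.inf,
                    **nanstat}
    return MetricRow(
        method=method, cluster_size=size, rr=rr, n_iterations=len(cfl),
        stats=stats, mce_rr=float(np.std(est, ddof=1)) if len(est) > 1 else np.nan,
        n_undefined_ppv=int(np.sum(~pd_)), n_undefined_npv=int(np.sum(~nd_)),
    )


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run (or resume) the full grid; returns and writes the tidy metric table."""
    out = Path(config.output_dir)
    cells_dir = out / "cells"
    cells_dir.mkdir(parents=True, exist_ok=True)
    dmap = config.load_map()
    scen = config.scenario

    all_rows: list[pd.DataFrame] = []
    for size in scen.cluster_sizes:
        for rr in scen.rr_levels:
            tag = f"size{size}_rr{rr:g}"
            cell_file = cells_dir / f"{tag}.csv"
            if cell_file.exists():
                try:
                    cached = pd.read_csv(cell_file)
                    if len(cached):
                        all_rows.append(cached)
                        log.info("cell %s: cached", tag)
                        continue
                except Exception:
                    pass  # partially written cell: re-run
            t0 = time.time()
            rows, raw = run_cell(dmap, size, rr, config)
            df = metrics_table(rows)
            df.to_csv(cell_file, index=False)
            if config.save_raw and raw:
                raw_dir = out / "raw"
                raw_dir.mkdir(exist_ok=True)
                (raw_dir / f"{tag}.json").write_text(json.dumps(
                    {"size": size, "rr": rr, "district_ids": dmap.district_ids,
                     "iterations": raw}))
            all_rows.append(df)
            log.info("cell %s: %d iterations, %.1fs, seed=%d", tag,
                     scen.iterations, time.time() - t0, scen.master_seed)

    table = pd.concat(all_rows, ignore_index=True)
    table.to_csv(out / "metrics.csv", index=False)
    (out / "run_metadata.json").write_text(json.dumps(
        {
            "master_seed": scen.master_seed,
            "iterations": scen.iterations,
            "baseline_rate": scen.baseline_rate,
            "years": scen.years,
            "rr_levels": list(scen.rr_levels),
            "cluster_sizes": list(scen.cluster_sizes),
            "methods": config.methods,
            "paired_clusters": config.paired_clusters,
            "H": dmap.H,
            "N": dmap.N,
        },
        indent=2,
    ))
    return table


def score_archive(
    raw_file: str | Path, dmap: DistrictMap, config: ExperimentConfig
) -> pd.DataFrame:
    """Re-score archived raw draws (clusters + case vectors) with the enabled methods."""
    payload = json.loads(Path(raw_file).read_text())
    ids = payload["district_ids"]
    if ids != dmap.district_ids:
        raise ValueError("archived draws were made on a different map")
    scen = config.scenario
    e = dmap.populations * scen.baseline_rate * scen.years
    size, rr = payload["size"], payload["rr"]
    confs: dict[str, list[Confusion]] = {m: [] for m in config.methods}
    est: dict[str, list[float]] = {m: [] for m in config.methods}
    for rec in payload["iterations"]:
        members = frozenset(dmap.index_of(d) for d in rec["member_ids"])
        cluster = TrueCluster(members, rec["target_size"], rec["rr"])
        cases = CaseVector(np.array(rec["cases"]), e)
        est_val = float(np.mean(cumulative_rr(cases)[list(members)]))
        labels = _run_methods(
            dmap, cluster, cases, config.methods,
            (size, 0, rec["iteration"]), scen.master_seed,
        )
        for m, lab in labels.items():
            if lab is not None:
                confs[m].append(confusion(lab, cluster, dmap))
                est[m].append(est_val)
    rows = [
        metrics_from_confusions(cfl, cfl[0].truth_size, np.array(est[m]),
                                method=m, cluster_size=size, rr=rr)
        for m, cfl in confs.items() if cfl
    ]
    return metrics_table(rows)
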