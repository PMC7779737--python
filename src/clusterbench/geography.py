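"""District geography: the map data model and its file formats.

A :class:`DistrictMap` bundles everything the detection methods need to know
about the study region: which administrative districts exist, which pairs
share a border (the binary adjacency relation ``W``), how many children under
15 live in each district (``u_i``), and where each district sits on the plane
(a centroid, used only to rank districts by distance).

Adjacency is accepted either as a square 0/1 CSV with district ids on both
the header row and the first column, or as a two-column edge list
(``id_a,id_b``).  Populations come from a two-column CSV
(``district_id,population``); centroids from a three-column CSV
(``district_id,x,y``) or a GeoJSON FeatureCollection whose features carry a
district id property.  All three sources are joined on district id, never on
row order.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DistrictMap",
    "MapValidationError",
    "load_district_map",
    "validate_map",
    "write_map_bundle",
    "read_map_bundle",
    "import_rdata",
]


class MapValidationError(ValueError):
    """A geography source violates the map contract (asymmetry, bad join, ...)."""


@dataclass
class DistrictMap:
    """Region graph: district ids, adjacency, under-15 populations, centroids.

    Parameters
    ----------
    district_ids
        Ordered opaque identifiers, one per district.
    adjacency
        Symmetric 0/1 matrix with zero diagonal; ``adjacency[i, j] = 1`` iff
        districts ``i`` and ``j`` share a border.
    populations
        Number of children under 15 per district (``u_i``); all positive.
    centroids
        ``(H, 2)`` array of planar ``(x, y)`` or ``(lon, lat)`` coordinates.
    lonlat
        If True, centroid distances use the great-circle metric instead of
        the Euclidean one.  Both only need to induce a consistent ranking of
        neighbors by distance.
    """

    district_ids: list[str]
    adjacency: np.ndarray
    populations: np.ndarray
    centroids: np.ndarray
    lonlat: bool = False
    _distance: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        self.populations = np.asarray(self.populations, dtype=float)
        self.centroids = np.asarray(self.centroids, dtype=float)
        self._validate()

    # -- invariants ------------------------------------------------------
    def _validate(self) -> None:
        H = len(self.district_ids)
        if len(set(self.district_ids)) != H:
            raise MapValidationError("district ids are not unique")
        if self.adjacency.shape != (H, H):
            raise MapValidationError(
                f"adjacency is {self.adjacency.shape}, expected ({H}, {H})"
            )
        asym = np.argwhere(self.adjacency != self.adjacency.T)
        if asym.size:
            i, j = asym[0]
            raise MapValidationError(
                "adjacency is not symmetric: "
                f"W[{self.district_ids[i]!r},{self.district_ids[j]!r}]="
                f"{self.adjacency[i, j]} but transpose is {self.adjacency[j, i]}"
            )
        if np.any(np.diag(self.adjacency) != 0):
            raise MapValidationError("adjacency has nonzero diagonal entries")
        if not np.isin(self.adjacency, (0, 1)).all():
            raise MapValidationError("adjacency entries must be 0 or 1")
        if self.populations.shape != (H,):
            raise MapValidationError("populations length does not match districts")
        bad = np.flatnonzero(~(self.populations > 0))
        if bad.size:
            raise MapValidationError(
                f"nonpositive population for districts "
                f"{[self.district_ids[i] for i in bad[:5]]}"
            )
        if self.centroids.shape != (H, 2):
            raise MapValidationError("centroids must be an (H, 2) array")
        uniq = {tuple(c) for c in self.centroids.round(12).tolist()}
        if len(uniq) != H:
            warnings.warn(
                "duplicate centroids present; distance ties broken by district id",
                stacklevel=2,
            )
        if nx.number_connected_components(self.graph()) > 1:
            warnings.warn(
                "adjacency graph is disconnected (islands present)", stacklevel=2
            )

    # -- derived quantities ----------------------------------------------
    @property
    def H(self) -> int:
        """Total number of districts."""
        return len(self.district_ids)

    @property
    def N(self) -> float:
        """Total population (sum of u_i)."""
        return float(self.populations.sum())

    @property
    def neighbor_counts(self) -> np.ndarray:
        """f_i: number of adjacent districts for each district."""
        return self.adjacency.sum(axis=1).astype(int)

    def graph(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        return g

    def index_of(self, district_id: str) -> int:
        return self.district_ids.index(district_id)

    def distance_matrix(self) -> np.ndarray:
        """All-pairs centroid distances (Euclidean, or great-circle if lonlat)."""
        if self._distance is None:
            if self.lonlat:
                self._distance = _haversine_matrix(self.centroids)
            else:
                d = self.centroids[:, None, :] - self.centroids[None, :, :]
                self._distance = np.sqrt((d**2).sum(axis=-1))
        return self._distance

    def neighbors_of(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.adjacency[i])


def _haversine_matrix(lonlat: np.ndarray) -> np.ndarray:
    """Great-circle distances in kilometres between (lon, lat) points."""
    lon = np.radians(lonlat[:, 0])
    lat = np.radians(lonlat[:, 1])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * (
        np.sin(dlon / 2) ** 2
    )
    return 2 * 6371.0 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


# ---------------------------------------------------------------------------
# loading


def load_district_map(
    adjacency_source: str | Path,
    population_source: str | Path,
    centroid_source: str | Path,
    lonlat: bool = False,
) -> DistrictMap:
    """Load and join the three geography sources into a validated DistrictMap.

    Identifiers are joined by district id, not by row order.  A dimension or
    id mismatch between sources raises :class:`MapValidationError` naming the
    offending ids.
    """
    adj_ids, W = _read_adjacency(Path(adjacency_source))
    pops = _read_populations(Path(population_source))
    cents = _read_centroids(Path(centroid_source))

    for name, other in (("population", set(pops)), ("centroid", set(cents))):
        missing = set(adj_ids) - other
        extra = other - set(adj_ids)
        if missing or extra:
            raise MapValidationError(
                f"{name} source does not align with adjacency: "
                f"missing={sorted(missing)[:5]} extra={sorted(extra)[:5]}"
            )

    u = np.array([pops[d] for d in adj_ids], dtype=float)
    xy = np.array([cents[d] for d in adj_ids], dtype=float)
    return DistrictMap(list(adj_ids), W, u, xy, lonlat=lonlat)


def _read_adjacency(path: Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] == 2:  # edge list id_a,id_b
        edges = df.values.tolist()
        ids = sorted({e for row in edges for e in row})
        idx = {d: i for i, d in enumerate(ids)}
        W = np.zeros((len(ids), len(ids)), dtype=np.int8)
        for a, b in edges:
            W[idx[a], idx[b]] = 1
            W[idx[b], idx[a]] = 1
        np.fill_diagonal(W, 0)
        return ids, W
    # square matrix with header row and id column
    ids = df.iloc[:, 0].astype(str).tolist()
    col_ids = [str(c) for c in df.columns[1:]]
    if ids != col_ids:
        raise MapValidationError(
            "adjacency matrix row ids do not match column ids "
            f"(first difference near {next((a for a, b in zip(ids, col_ids) if a != b), '?')!r})"
        )
    W = df.iloc[:, 1:].to_numpy(dtype=float)
    if W.shape[0] != W.shape[1]:
        raise MapValidationError(f"adjacency matrix is not square: {W.shape}")
    return ids, W.astype(np.int8)


def _read_populations(path: Path) -> dict[str, float]:
    df = pd.read_csv(path)
    id_col, pop_col = df.columns[0], df.columns[1]
    return {str(r[id_col]): float(r[pop_col]) for _, r in df.iterrows()}


def _read_centroids(path: Path) -> dict[str, tuple[float, float]]:
    if path.suffix.lower() in {".geojson", ".json"}:
        return _centroids_from_geojson(path)
    df = pd.read_csv(path)
    c0, c1, c2 = df.columns[:3]
    return {str(r[c0]): (float(r[c1]), float(r[c2])) for _, r in df.iterrows()}


def _centroids_from_geojson(path: Path) -> dict[str, tuple[float, float]]:
    """Point-on-surface of each feature, keyed by its district id property."""
    from shapely.geometry import shape

    gj = json.loads(Path(path).read_text())
    out: dict[str, tuple[float, float]] = {}
    for feat in gj["features"]:
        props = feat.get("properties") or {}
        fid = None
        for key in ("district_id", "id", "NAME_3", "CC_3", "name"):
            if key in props:
                fid = str(props[key])
                break
        if fid is None:
            fid = str(feat.get("id"))
        geom = shape(feat["geometry"])
        p = geom if geom.geom_type == "Point" else geom.representative_point()
        out[fid] = (p.x, p.y)
    return out


# ---------------------------------------------------------------------------
# diagnostics


def validate_map(dmap: DistrictMap) -> dict:
    """Pure diagnostic report: components, neighbor counts, population spread."""
    g = dmap.graph()
    comps = list(nx.connected_components(g))
    f = dmap.neighbor_counts
    q = np.percentile(dmap.populations, [0, 25, 50, 75, 100])
    return {
        "n_districts": dmap.H,
        "n_components": len(comps),
        "component_sizes": sorted((len(c) for c in comps), reverse=True),
        "isolated_districts": [dmap.district_ids[i] for i in np.flatnonzero(f == 0)],
        "neighbor_counts": {
            "min": int(f.min()),
            "mean": float(f.mean()),
            "max": int(f.max()),
        },
        "population": {
            "total": dmap.N,
            "quantiles": {k: float(v) for k, v in zip(["min", "q25", "median", "q75", "max"], q)},
        },
    }


# ---------------------------------------------------------------------------
# canonical bundle


def write_map_bundle(dmap: DistrictMap, directory: str | Path) -> Path:
    """Write the canonical bundle: three CSVs plus JSON metadata with checksums."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    ids = dmap.district_ids

    adj = pd.DataFrame(dmap.adjacency, index=ids, columns=ids)
    adj.to_csv(d / "adjacency.csv", index_label="district_id")
    pd.DataFrame({"district_id": ids, "population": dmap.populations}).to_csv(
        d / "populations.csv", index=False
    )
    pd.DataFrame(
        {"district_id": ids, "x": dmap.centroids[:, 0], "y": dmap.centroids[:, 1]}
    ).to_csv(d / "centroids.csv", index=False)

    meta = {
        "H": dmap.H,
        "N": dmap.N,
        "lonlat": dmap.lonlat,
        "checksums": {
            f.name: hashlib.md5(f.read_bytes()).hexdigest()
            for f in (d / "adjacency.csv", d / "populations.csv", d / "centroids.csv")
        },
    }
    (d / "metadata.json").write_text(json.dumps(meta, indent=2))
    return d


def read_map_bundle(directory: str | Path) -> DistrictMap:
    d = Path(directory)
    meta = json.loads((d / "metadata.json").read_text())
    return load_district_map(
        d / "adjacency.csv",
        d / "populations.csv",
        d / "centroids.csv",
        lonlat=bool(meta.get("lonlat", False)),
    )


def import_rdata(path: str | Path, out_dir: str | Path) -> Path:  # pragma: no cover
    """Convert a deposited RData geography into the canonical CSV bundle.

    The conversion needs the optional ``pyreadr`` reader; when it is absent
    an ImportError points at the CSV dialect the core pipeline reads.
    """
    try:
        import pyreadr  # type: ignore
    except ImportError as exc:
        raise ImportError(
            "RData import needs the optional 'pyreadr' package; convert the "
            "deposit to the CSV dialect (square adjacency CSV, "
            "district_id/population CSV, district_id/x/y CSV) instead"
        ) from exc
    raise NotImplementedError(
        "supply adjacency/population/centroid objects via load_district_map"
    )
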