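"""Areal contiguity graphs, spatial lags and spatial autocorrelation tests.

The central object is :class:`AreaGraph`, a set of areal units (census
tracts, grid cells, ...) together with a binary first-order contiguity
structure.  Adjacency can be derived from polygon geometry (queen or rook
rule) or supplied directly as an edge list.  On top of the graph the module
provides row-standardized spatial lags (neighborhood averages of a
covariate) and Moran's I with a permutation test, the standard screen for
spatial autocorrelation in areal data.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from shapely.geometry import mapping, shape
from shapely.strtree import STRtree

__all__ = [
    "AreaGraph",
    "build_adjacency",
    "read_geojson",
    "read_adjacency_csv",
    "spatial_lag",
    "morans_i",
    "morans_i_permutation",
]


class IslandWarning(UserWarning):
    """A unit with no neighbors was retained in the graph."""


@dataclass(eq=False)
class AreaGraph:
    """Areal units with binary first-order contiguity.

    Parameters
    ----------
    unit_ids
        Ordered unit identifiers (length K, unique).
    edges
        Unordered adjacent pairs as ``(i, j)`` index pairs with ``i < j``,
        sorted canonically.
    geometry
        Optional shapely polygon per unit.
    centroids
        Optional ``(K, 2)`` planar centroid coordinates.
    """

    unit_ids: tuple
    edges: tuple
    geometry: tuple | None = None
    centroids: np.ndarray | None = None
    island_ids: tuple = field(default=())

    def __post_init__(self) -> None:
        ids = tuple(self.unit_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("unit_ids must be unique")
        self.unit_ids = ids
        K = len(ids)
        canon = set()
        for i, j in self.edges:
            if not (0 <= i < K and 0 <= j < K):
                raise ValueError(f"edge ({i}, {j}) out of range for K={K}")
            if i == j:
                raise ValueError(f"self-edge on unit index {i}")
            canon.add((min(i, j), max(i, j)))
        self.edges = tuple(sorted(canon))
        deg = np.zeros(K, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        islands = tuple(ids[k] for k in range(K) if deg[k] == 0)
        if islands and not self.island_ids:
            self.island_ids = islands
        if self.centroids is None and self.geometry is not None:
            self.centroids = np.array(
                [[g.centroid.x, g.centroid.y] for g in self.geometry]
            )

    # ------------------------------------------------------------------
    @property
    def K(self) -> int:
        return len(self.unit_ids)

    @cached_property
    def index(self) -> dict:
        return {uid: k for k, uid in enumerate(self.unit_ids)}

    @cached_property
    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Edge endpoints as two int arrays ``(ei, ej)`` with ``ei < ej``."""
        if not self.edges:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        arr = np.asarray(self.edges, dtype=int)
        return arr[:, 0], arr[:, 1]

    @cached_property
    def degrees(self) -> np.ndarray:
        ei, ej = self.edge_arrays
        deg = np.bincount(ei, minlength=self.K) + np.bincount(ej, minlength=self.K)
        return deg

    @cached_property
    def neighbors(self) -> list:
        nbrs: list[list[int]] = [[] for _ in range(self.K)]
        for i, j in self.edges:
            nbrs[i].append(j)
            nbrs[j].append(i)
        return [np.array(sorted(n), dtype=int) for n in nbrs]

    @cached_property
    def W(self) -> np.ndarray:
        """Dense binary adjacency matrix (symmetric, zero diagonal)."""
        W = np.zeros((self.K, self.K))
        ei, ej = self.edge_arrays
        W[ei, ej] = 1.0
        W[ej, ei] = 1.0
        return W

    @cached_property
    def W_sparse(self) -> sparse.csr_matrix:
        ei, ej = self.edge_arrays
        data = np.ones(2 * len(ei))
        return sparse.coo_matrix(
            (data, (np.concatenate([ei, ej]), np.concatenate([ej, ei]))),
            shape=(self.K, self.K),
        ).tocsr()

    def edge_ids(self) -> list:
        """Edges as canonical ``(min_id, max_id)`` unit-id pairs."""
        out = []
        for i, j in self.edges:
            a, b = self.unit_ids[i], self.unit_ids[j]
            out.append((a, b) if str(a) <= str(b) else (b, a))
        return out

    # ------------------------------------------------------------------
    @classmethod
    def from_edge_ids(cls, unit_ids: Sequence, id_pairs: Iterable) -> "AreaGraph":
        """Build a graph from unit ids and an iterable of id pairs."""
        ids = tuple(unit_ids)
        index = {uid: k for k, uid in enumerate(ids)}
        edges = []
        for a, b in id_pairs:
            if a not in index or b not in index:
                raise ValueError(f"edge ({a}, {b}) references unknown unit id")
            edges.append((index[a], index[b]))
        g = cls(unit_ids=ids, edges=tuple(edges))
        if g.island_ids:
            warnings.warn(
                f"units with no neighbors retained: {g.island_ids}", IslandWarning,
                stacklevel=2,
            )
        return g

    def write_edges_csv(self, path) -> None:
        """Write the edge list as CSV with canonical (min_id, max_id) order."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id_i", "id_j"])
            for a, b in sorted(self.edge_ids(), key=lambda p: (str(p[0]), str(p[1]))):
                w.writerow([a, b])


# ----------------------------------------------------------------------
def build_adjacency(polygons: Sequence, unit_ids: Sequence | None = None,
                    rule: str = "queen") -> AreaGraph:
    """Derive first-order contiguity from planar polygons.

    ``queen`` links units sharing at least one boundary point; ``rook``
    requires a shared boundary segment of positive length.  Units with no
    neighbors (islands) are retained with a warning.
    """
    if rule not in ("queen", "rook"):
        raise ValueError(f"rule must be 'queen' or 'rook', got {rule!r}")
    polygons = list(polygons)
    if not polygons:
        raise ValueError("no polygons supplied")
    if unit_ids is None:
        unit_ids = tuple(range(len(polygons)))
    unit_ids = tuple(unit_ids)
    if len(unit_ids) != len(polygons):
        raise ValueError("unit_ids and polygons length mismatch")
    for uid, g in zip(unit_ids, polygons):
        if g is None or g.is_empty:
            raise ValueError(f"unit {uid!r} has empty geometry")
        if not g.is_valid:
            raise ValueError(f"unit {uid!r} has invalid geometry")

    tree = STRtree(polygons)
    left, right = tree.query(polygons, predicate="intersects")
    edges = set()
    for i, j in zip(left.tolist(), right.tolist()):
        if i >= j:
            continue
        inter = polygons[i].intersection(polygons[j])
        if inter.is_empty:
            continue
        if rule == "rook" and inter.length <= 0:
            continue
        edges.add((i, j))

    g = AreaGraph(unit_ids=unit_ids, edges=tuple(sorted(edges)),
                  geometry=tuple(polygons))
    if g.island_ids:
        warnings.warn(
            f"units with no neighbors retained: {g.island_ids}", IslandWarning,
            stacklevel=2,
        )
    return g


def read_geojson(path, id_property: str = "id", rule: str = "queen") -> AreaGraph:
    """Read a GeoJSON FeatureCollection of polygons and build contiguity.

    Unit ids are taken from ``properties[id_property]``, falling back to the
    feature-level ``id`` member, then to the feature index.
    """
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj.get("features", [])
    if not feats:
        raise ValueError(f"no features in {path}")
    polygons, ids = [], []
    for k, feat in enumerate(feats):
        props = feat.get("properties") or {}
        uid = props.get(id_property, feat.get("id", k))
        ids.append(uid)
        polygons.append(shape(feat["geometry"]))
    return build_adjacency(polygons, ids, rule=rule)


def write_geojson(graph: AreaGraph, path, properties: dict | None = None) -> None:
    """Write the graph's polygons as a GeoJSON FeatureCollection.

    ``properties`` maps column name -> per-unit sequence.
    """
    if graph.geometry is None:
        raise ValueError("graph has no geometry")
    feats = []
    for k, uid in enumerate(graph.unit_ids):
        props = {"id": uid}
        if properties:
            for name, col in properties.items():
                v = col[k]
                props[name] = v.item() if hasattr(v, "item") else v
        feats.append({
            "type": "Feature",
            "properties": props,
            "geometry": mapping(graph.geometry[k]),
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_adjacency_csv(path, unit_ids: Sequence | None = None) -> AreaGraph:
    """Read an adjacency list CSV with columns ``id_i, id_j``.

    If ``unit_ids`` is not given, units are the sorted distinct ids in the
    file (a unit that appears only as an island cannot be represented this
    way; pass ``unit_ids`` explicitly to retain it).
    """
    pairs = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"id_i", "id_j"} <= set(reader.fieldnames):
            raise ValueError(f"{path} must have columns id_i, id_j")
        for row in reader:
            pairs.append((row["id_i"], row["id_j"]))
    if unit_ids is None:
        unit_ids = sorted({a for a, _ in pairs} | {b for _, b in pairs})
    return AreaGraph.from_edge_ids(unit_ids, pairs)


# ----------------------------------------------------------------------
def spatial_lag(graph: AreaGraph, x, mode: str = "mean") -> np.ndarray:
    """Spatial lag of ``x``: neighborhood average (row-standardized weights).

    ``mode='mean'`` (default) returns the average of ``x`` over each unit's
    neighbors; ``mode='sum'`` returns the binary-weight sum.  Islands get
    NaN under ``mode='mean'`` (their average is undefined) and 0 under
    ``mode='sum'``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (graph.K,):
        raise ValueError(f"x must have length K={graph.K}")
    if not np.all(np.isfinite(x)):
        raise ValueError("x contains missing or non-finite values")
    deg = graph.degrees
    if np.all(deg == 0):
        raise ValueError("all units are islands; spatial lag undefined")
    ei, ej = graph.edge_arrays
    s = np.bincount(ei, weights=x[ej], minlength=graph.K)
    s += np.bincount(ej, weights=x[ei], minlength=graph.K)
    if mode == "sum":
        return s
    if mode != "mean":
        raise ValueError(f"mode must be 'mean' or 'sum', got {mode!r}")
    out = np.full(graph.K, np.nan)
    nz = deg > 0
    out[nz] = s[nz] / deg[nz]
    return out


def _moran_prepare(graph: AreaGraph, x) -> tuple[np.ndarray, float]:
    x = np.asarray(x, dtype=float)
    if x.shape != (graph.K,):
        raise ValueError(f"x must have length K={graph.K}")
    if graph.K < 3:
        raise ValueError("Moran's I requires at least 3 units")
    xc = x - x.mean()
    den = float(xc @ xc)
    if den <= 0:
        raise ValueError("x has zero variance; Moran's I undefined")
    return xc, den


def morans_i(graph: AreaGraph, x) -> float:
    """Classic Moran's I with binary weights.

    ``I = (K / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_k (x_k - xbar)^2``
    with ``S0 = sum_ij w_ij = 2 * |edges|``.
    """
    xc, den = _moran_prepare(graph, x)
    ei, ej = graph.edge_arrays
    if len(ei) == 0:
        raise ValueError("graph has no edges; Moran's I undefined")
    num = 2.0 * float(xc[ei] @ xc[ej])
    s0 = 2.0 * len(ei)
    return (graph.K / s0) * num / den


def morans_i_permutation(graph: AreaGraph, x, n_perm: int = 999,
                         seed: int | None = None,
                         alternative: str = "greater") -> tuple[float, float]:
    """Permutation test for Moran's I.

    Returns ``(I_observed, pseudo_p)`` with the +1-corrected pseudo p-value
    ``(1 + #{I_perm >= I_obs}) / (1 + n_perm)`` for the upper-tail test.
    ``alternative='two-sided'`` counts permuted values at least as far from
    the null expectation ``-1/(K-1)`` as the observed one.  Deterministic
    for a fixed ``seed``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    xc, den = _moran_prepare(graph, x)
    ei, ej = graph.edge_arrays
    if len(ei) == 0:
        raise ValueError("graph has no edges; Moran's I undefined")
    s0 = 2.0 * len(ei)
    scale = graph.K / (s0 * den)
    obs = scale * 2.0 * float(xc[ei] @ xc[ej])

    rng = np.random.default_rng(seed)
    # permuting x leaves the centered sum of squares unchanged
    perms = rng.permuted(np.tile(xc, (n_perm, 1)), axis=1)
    perm_i = scale * 2.0 * np.sum(perms[:, ei] * perms[:, ej], axis=1)
    if alternative == "greater":
        count = int(np.sum(perm_i >= obs))
    else:
        e0 = -1.0 / (graph.K - 1)
        count = int(np.sum(np.abs(perm_i - e0) >= abs(obs - e0)))
    p = (1.0 + count) / (1.0 + n_perm)
    return obs, p
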