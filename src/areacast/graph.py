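"""Areal adjacency structures for disease-mapping models.

An :class:`ArealGraph` records which small areas (ZCTAs, grid cells, ...)
are neighbours.  It is the backbone of the conditional autoregressive
(CAR) spatial priors: two areas are conditionally dependent exactly when
they share an edge here.  Areas are always ordered lexicographically by
identifier so that matrix rows/columns mean the same thing in every
module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from shapely import STRtree
from shapely.geometry import shape as _shapely_shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "ArealGraph",
    "build_graph_from_polygons",
    "build_graph_from_edgelist",
    "grid_graph",
    "read_geojson_polygons",
    "read_edgelist",
    "write_adjacency",
    "read_adjacency",
]


@dataclass
class ArealGraph:
    """Symmetric binary adjacency over a fixed, ordered set of areas.

    Attributes
    ----------
    area_ids
        Area identifiers, sorted lexicographically.
    adjacency
        ``I x I`` sparse symmetric 0/1 matrix with zero diagonal.
    component_labels
        Connected-component label per area.
    """

    area_ids: list[str]
    adjacency: sp.csr_matrix
    component_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.adjacency = sp.csr_matrix(self.adjacency)
        if self.adjacency.shape != (self.n_areas, self.n_areas):
            raise ValueError("adjacency shape does not match number of areas")
        if (abs(self.adjacency - self.adjacency.T)).nnz:
            raise ValueError("adjacency must be symmetric")
        if self.adjacency.diagonal().any():
            raise ValueError("adjacency must have zero diagonal")
        if self.component_labels is None:
            _, labels = connected_components(self.adjacency, directed=False)
            self.component_labels = labels
        self.component_labels = np.asarray(self.component_labels)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_components(self) -> int:
        return int(self.component_labels.max()) + 1 if self.n_areas else 0

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    @property
    def neighbor_counts(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    @property
    def island_mask(self) -> np.ndarray:
        """Boolean mask of areas with no neighbours."""
        return self.neighbor_counts == 0

    @property
    def n_islands(self) -> int:
        return int(self.island_mask.sum())

    def index_of(self, area_id: str) -> int:
        return self.area_ids.index(area_id)


def _finalize(area_ids: list[str], rows: list[int], cols: list[int]) -> ArealGraph:
    n = len(area_ids)
    data = np.ones(len(rows))
    W = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    W.data[:] = 1.0  # collapse duplicate entries to binary
    return ArealGraph(area_ids=area_ids, adjacency=W)


def build_graph_from_polygons(
    geometries: dict[str, BaseGeometry], rule: str = "queen"
) -> ArealGraph:
    """Contiguity graph from polygon geometries keyed by area id.

    Under the ``queen`` rule two areas are neighbours if their geometries
    share at least a point; under ``rook`` they must share a boundary of
    positive length.
    """
    if not geometries:
        raise ValueError("empty geometry collection")
    ids = list(geometries)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate area ids in geometry collection")
    if rule not in ("queen", "rook"):
        raise ValueError(f"unknown contiguity rule {rule!r}")
    area_ids = sorted(ids)
    geoms = [geometries[a] for a in area_ids]
    tree = STRtree(geoms)
    rows: list[int] = []
    cols: list[int] = []
    for i, g in enumerate(geoms):
        for j in tree.query(g, predicate="intersects"):
            j = int(j)
            if j <= i:
                continue
            inter = g.intersection(geoms[j])
            if inter.is_empty:
                continue
            if rule == "rook":
                # require a shared boundary segment, not just corner points
                if inter.length == 0 and inter.area == 0:
                    continue
            rows += [i, j]
            cols += [j, i]
    return _finalize(area_ids, rows, cols)


def build_graph_from_edgelist(
    area_ids: list[str], edges: list[tuple[str, str]]
) -> ArealGraph:
    """Graph from declared areas plus an explicit neighbour list."""
    if len(set(area_ids)) != len(area_ids):
        raise ValueError("duplicate area ids")
    ordered = sorted(str(a) for a in area_ids)
    index = {a: i for i, a in enumerate(ordered)}
    rows: list[int] = []
    cols: list[int] = []
    for a, b in edges:
        a, b = str(a), str(b)
        if a == b:
            raise ValueError(f"self-loop on area {a!r}")
        for x in (a, b):
            if x not in index:
                raise ValueError(f"unknown area id {x!r} in edge list")
        rows += [index[a], index[b]]
        cols += [index[b], index[a]]
    return _finalize(ordered, rows, cols)


def grid_graph(n_rows: int, n_cols: int, rule: str = "rook") -> ArealGraph:
    """Regular lattice graph; a synthetic stand-in for a real areal map.

    Area ids are ``r{row:03d}c{col:03d}`` so lexicographic order equals
    row-major order.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    if rule not in ("queen", "rook"):
        raise ValueError(f"unknown contiguity rule {rule!r}")
    ids = [f"r{r:03d}c{c:03d}" for r in range(n_rows) for c in range(n_cols)]
    rows: list[int] = []
    cols: list[int] = []

    def idx(r: int, c: int) -> int:
        return r * n_cols + c

    steps = [(0, 1), (1, 0)]
    if rule == "queen":
        steps += [(1, 1), (1, -1)]
    for r in range(n_rows):
        for c in range(n_cols):
            for dr, dc in steps:
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    rows += [idx(r, c), idx(rr, cc)]
                    cols += [idx(rr, cc), idx(r, c)]
    return _finalize(ids, rows, cols)


# ---------------------------------------------------------------------------
# File formats


def read_geojson_polygons(path: str | Path, id_property: str = "id") -> dict[str, BaseGeometry]:
    """Read a GeoJSON FeatureCollection into ``{area_id: geometry}``.

    The id is taken from the feature ``id`` member, falling back to the
    property named by ``id_property``.
    """
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    out: dict[str, BaseGeometry] = {}
    for f in feats:
        fid = f.get("id", f.get("properties", {}).get(id_property))
        if fid is None:
            raise ValueError("feature without id")
        fid = str(fid)
        if fid in out:
            raise ValueError(f"duplicate area id {fid!r}")
        out[fid] = _shapely_shape(f["geometry"])
    return out


def read_edgelist(path: str | Path) -> list[tuple[str, str]]:
    """Two whitespace-separated ids per line; '#' starts a comment."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            a, b = line.split()
            edges.append((a, b))
    return edges


def write_adjacency(graph: ArealGraph, path: str | Path) -> None:
    """Write each undirected edge once as ``id1 id2`` per line."""
    coo = sp.triu(graph.adjacency).tocoo()
    with open(path, "w") as fh:
        fh.write("# adjacency edge list, one undirected edge per line\n")
        for i, j in zip(coo.row, coo.col):
            fh.write(f"{graph.area_ids[i]} {graph.area_ids[j]}\n")
        # islands appear nowhere in the edge list; record ids so the
        # graph round-trips
        for i in np.flatnonzero(graph.island_mask):
            fh.write(f"# island {graph.area_ids[i]}\n")


def read_adjacency(path: str | Path, area_ids: list[str] | None = None) -> ArealGraph:
    edges = read_edgelist(path)
    if area_ids is None:
        seen: set[str] = set()
        with open(path) as fh:
            for line in fh:
                if line.startswith("# island "):
                    seen.add(line.split()[-1])
        for a, b in edges:
            seen.update((a, b))
        area_ids = sorted(seen)
    return build_graph_from_edgelist(area_ids, edges)
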