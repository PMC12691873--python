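"""Binary contiguity structures over regions.

The spatial stages of the package (Moran's I, Moran eigenvector filtering)
operate on a symmetric binary spatial weights matrix ``C`` in which
``C[i, j] = 1`` when regions *i* and *j* share a boundary.  This module
builds, validates and serializes that structure.  Weights are deliberately
*not* row-standardized: the doubly centered matrix used for eigenvector
extraction and the Moran statistics both consume the raw 0/1 matrix.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AdjacencyGraph",
    "build_adjacency",
    "contiguity_from_polygons",
    "connected_components",
    "read_gal",
    "write_gal",
    "read_edge_csv",
    "write_edge_csv",
    "read_geojson",
]


class SpatialWeightsError(ValueError):
    """Invalid region/edge structure (self-loop, unknown label, duplicate)."""


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric binary contiguity graph over labelled regions.

    Parameters
    ----------
    region_ids :
        Ordered, unique region labels. The order fixes the row/column order
        of the weights matrix and of every per-region vector downstream.
    edges :
        Unordered region-label pairs, stored deduplicated with each pair
        ordered by position in ``region_ids``.
    """

    region_ids: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    _index: dict[str, int] = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        object.__setattr__(
            self, "_index", {r: i for i, r in enumerate(self.region_ids)}
        )

    @property
    def n(self) -> int:
        return len(self.region_ids)

    @property
    def s0(self) -> int:
        """Sum of all weights, 1'C1 = 2 * |edges|."""
        return 2 * len(self.edges)

    def index_of(self, label: str) -> int:
        return self._index[label]

    def edge_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Edge endpoints as two parallel integer arrays (one row per edge)."""
        if not self.edges:
            return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
        pairs = sorted(
            (self._index[a], self._index[b]) for a, b in self.edges
        )
        arr = np.asarray(pairs, dtype=np.intp)
        return arr[:, 0], arr[:, 1]

    def matrix(self) -> np.ndarray:
        """Dense n x n symmetric 0/1 weights matrix with zero diagonal."""
        C = np.zeros((self.n, self.n))
        i, j = self.edge_indices()
        C[i, j] = 1.0
        C[j, i] = 1.0
        return C

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n)
        i, j = self.edge_indices()
        np.add.at(deg, i, 1.0)
        np.add.at(deg, j, 1.0)
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.region_ids)
        g.add_edges_from(self.edges)
        return g


def build_adjacency(
    region_ids: Sequence[str], edges: Iterable[tuple[str, str]]
) -> AdjacencyGraph:
    """Build a validated :class:`AdjacencyGraph`.

    Duplicate and mirrored pairs are deduplicated; the input region order is
    preserved. Raises :class:`SpatialWeightsError` on duplicate labels,
    self-loops, or edge endpoints not among the labels.
    """
    ids = [str(r) for r in region_ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({r for r in ids if r in seen or seen.add(r)})
        raise SpatialWeightsError(f"duplicate region labels: {dups}")
    index = {r: i for i, r in enumerate(ids)}
    dedup: set[tuple[str, str]] = set()
    for a, b in edges:
        a, b = str(a), str(b)
        if a not in index or b not in index:
            missing = [x for x in (a, b) if x not in index]
            raise SpatialWeightsError(f"edge endpoint(s) not among regions: {missing}")
        if a == b:
            raise SpatialWeightsError(f"self-loop on region {a!r}")
        if index[a] > index[b]:
            a, b = b, a
        dedup.add((a, b))
    return AdjacencyGraph(tuple(ids), frozenset(dedup))


def contiguity_from_polygons(
    polygons: Sequence[tuple[str, "shapely.Geometry"]],  # noqa: F821
    rule: str = "queen",
) -> AdjacencyGraph:
    """Contiguity graph from labelled polygons.

    ``queen``: any shared boundary point creates an edge.  ``rook``: the
    shared boundary must have positive length (corner contacts excluded).
    """
    from shapely import STRtree
    from shapely.validation import explain_validity

    if rule not in {"queen", "rook"}:
        raise ValueError(f"rule must be 'queen' or 'rook', got {rule!r}")
    labels = [str(lbl) for lbl, _ in polygons]
    if len(set(labels)) != len(labels):
        raise SpatialWeightsError("duplicate polygon labels")
    geoms = [geom for _, geom in polygons]
    for lbl, geom in zip(labels, geoms):
        if geom is None or geom.is_empty or not geom.is_valid:
            reason = "empty" if geom is None or geom.is_empty else explain_validity(geom)
            raise SpatialWeightsError(f"invalid geometry for region {lbl!r}: {reason}")
    tree = STRtree(geoms)
    edges: set[tuple[str, str]] = set()
    for i, geom in enumerate(geoms):
        for j in tree.query(geom, predicate="intersects"):
            j = int(j)
            if j <= i:
                continue
            inter = geom.intersection(geoms[j])
            if inter.is_empty:
                continue
            if rule == "queen" or inter.length > 0:
                edges.add((labels[i], labels[j]))
    return build_adjacency(labels, edges)


def connected_components(graph: AdjacencyGraph) -> list[set[str]]:
    """Partition of ``region_ids`` into connected components.

    A disconnected weights structure is legal (the doubly centered matrix is
    still well defined) but usually indicates islands or data problems, so a
    warning is logged when more than one component is found.
    """
    comps = [set(c) for c in nx.connected_components(graph.to_networkx())]
    if len(comps) > 1:
        logger.warning("adjacency graph has %d connected components", len(comps))
        warnings.warn(
            f"adjacency graph has {len(comps)} connected components",
            stacklevel=2,
        )
    return comps


# ---------------------------------------------------------------------------
# serialization


def write_gal(graph: AdjacencyGraph, path) -> None:
    """Write the graph in GAL neighbour-list format."""
    with open(path, "w") as fh:
        fh.write(f"{graph.n}\n")
        nbrs: dict[str, list[str]] = {r: [] for r in graph.region_ids}
        for a, b in sorted(graph.edges, key=lambda e: (graph.index_of(e[0]), graph.index_of(e[1]))):
            nbrs[a].append(b)
            nbrs[b].append(a)
        for r in graph.region_ids:
            ns = sorted(nbrs[r], key=graph.index_of)
            fh.write(f"{r} {len(ns)}\n")
            fh.write(" ".join(ns) + "\n")


def read_gal(path) -> AdjacencyGraph:
    with open(path) as fh:
        tokens_header = fh.readline().split()
        n = int(tokens_header[0])  # some GAL dialects put n last on a 4-token header
        if len(tokens_header) == 4:
            n = int(tokens_header[1])
        ids: list[str] = []
        edges: list[tuple[str, str]] = []
        for _ in range(n):
            label, count = fh.readline().split()
            ids.append(label)
            ns = fh.readline().split()
            if len(ns) != int(count):
                raise SpatialWeightsError(
                    f"GAL record for {label!r} promises {count} neighbours, got {len(ns)}"
                )
            edges.extend((label, nb) for nb in ns)
    return build_adjacency(ids, edges)


def write_edge_csv(graph: AdjacencyGraph, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["region_a", "region_b"])
        for a, b in sorted(
            graph.edges, key=lambda e: (graph.index_of(e[0]), graph.index_of(e[1]))
        ):
            w.writerow([a, b])


def read_edge_csv(path, region_ids: Sequence[str] | None = None) -> AdjacencyGraph:
    """Read a two-column edge list. When ``region_ids`` is omitted the label
    universe is inferred from the edges (isolated regions are then invisible)."""
    edges = []
    with open(path, newline="") as fh:
        rdr = csv.reader(fh)
        header = next(rdr)
        if len(header) < 2:
            raise SpatialWeightsError("edge CSV needs two label columns")
        for row in rdr:
            if row:
                edges.append((row[0], row[1]))
    if region_ids is None:
        seen: list[str] = []
        met = set()
        for a, b in edges:
            for x in (a, b):
                if x not in met:
                    met.add(x)
                    seen.append(x)
        region_ids = seen
    return build_adjacency(region_ids, edges)


def read_geojson(path, label_property: str, rule: str = "queen") -> AdjacencyGraph:
    """Contiguity graph from a GeoJSON FeatureCollection of polygons."""
    from shapely.geometry import shape

    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise SpatialWeightsError("expected a GeoJSON FeatureCollection")
    polys = []
    for feat in doc["features"]:
        props = feat.get("properties") or {}
        if label_property not in props:
            raise SpatialWeightsError(
                f"feature missing label property {label_property!r}"
            )
        polys.append((str(props[label_property]), shape(feat["geometry"])))
    return contiguity_from_polygons(polys, rule=rule)
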