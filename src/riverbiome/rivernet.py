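"""Dendritic river networks and per-site geographic distance measures.

A river network is a rooted in-tree: every reach drains toward a single
outlet, edges point downstream (child = upstream node, parent = the node
it flows into), each edge carries a reach length in km, and each node
the area (km^2) of its own subcatchment. Three per-site scalars
summarize a station's position in the network:

* **site catchment area** — total drainage area upstream of (and
  including) the site;
* **cumulative dendritic distance** — the summed lengths of every
  headwater-to-site path, a proxy for upstream network density;
* **mean dendritic distance** — the average of those path lengths, a
  proxy for water residence time.

Pairwise geographic distance between sites is the absolute difference
of the chosen scalar (the minimal monotone construction when only
per-site scalars are defined); the along-network flow distance between
site pairs is also available as a fourth option.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from skbio import DistanceMatrix

__all__ = [
    "RiverNetworkError",
    "RiverNetwork",
    "SiteGeoMeasures",
    "load_network",
    "write_network",
    "site_geo_measures",
    "all_geo_measures",
    "pairwise_geo_distance",
]


class RiverNetworkError(ValueError):
    """Structural error in a river-network edge list."""


@dataclasses.dataclass
class SiteGeoMeasures:
    station_id: str
    catchment_area_km2: float
    cumulative_dendritic_km: float
    mean_dendritic_km: float
    n_paths: int


class RiverNetwork:
    """Rooted directed dendritic graph of river reaches.

    Edges run upstream node -> downstream node with attribute
    ``length_km``; nodes carry ``subcatchment_area_km2``. Exactly one
    node (the outlet) has no downstream edge.
    """

    def __init__(self, graph: nx.DiGraph):
        self.graph = graph
        self.outlet = self._validate()

    def _validate(self) -> str:
        g = self.graph
        if g.number_of_nodes() == 0:
            raise RiverNetworkError("empty network")
        roots = [v for v in g.nodes if g.out_degree(v) == 0]
        if len(roots) != 1:
            raise RiverNetworkError(f"expected a single outlet, found {sorted(roots)}")
        multi = [v for v in g.nodes if g.out_degree(v) > 1]
        if multi:
            raise RiverNetworkError(f"node(s) with more than one downstream reach: {sorted(multi)}")
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise RiverNetworkError(f"cycle detected: {cycle}")
        if not nx.is_weakly_connected(g):
            comps = sorted(nx.weakly_connected_components(g), key=len)
            raise RiverNetworkError(f"disconnected node(s): {sorted(comps[0])}")
        for u, v, data in g.edges(data=True):
            if not data.get("length_km", 0) > 0:
                raise RiverNetworkError(f"non-positive reach length on edge {u}->{v}")
        for v, data in g.nodes(data=True):
            if data.get("subcatchment_area_km2", 0.0) < 0:
                raise RiverNetworkError(f"negative subcatchment area at node {v}")
        return roots[0]

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float, float]],
        outlet_area_km2: float = 0.0,
    ) -> "RiverNetwork":
        """Build from (child, parent, length_km, child_subcatchment_area_km2) rows.

        The outlet never appears as a child, so its own subcatchment
        area is supplied separately (default 0).
        """
        g = nx.DiGraph()
        for child, parent, length, area in edges:
            if g.has_edge(child, parent):
                raise RiverNetworkError(f"duplicate edge {child}->{parent}")
            g.add_edge(child, parent, length_km=float(length))
            g.nodes[child]["subcatchment_area_km2"] = float(area)
        for v in g.nodes:
            g.nodes[v].setdefault("subcatchment_area_km2", float(outlet_area_km2))
        return cls(g)

    @property
    def stations(self) -> list[str]:
        return sorted(self.graph.nodes)

    def upstream_nodes(self, station: str) -> set[str]:
        """All nodes draining through `station`, excluding the station itself."""
        if station not in self.graph:
            raise RiverNetworkError(f"unknown station {station!r}")
        return nx.ancestors(self.graph, station)

    def headwaters(self) -> list[str]:
        return [v for v in self.graph.nodes if self.graph.in_degree(v) == 0]

    def to_graphml(self, path: str | Path, measures: pd.DataFrame | None = None) -> None:
        g = self.graph.copy()
        if measures is not None:
            for _, row in measures.iterrows():
                if row["station_id"] in g:
                    for col in ("catchment_area_km2", "cumulative_dendritic_km", "mean_dendritic_km"):
                        g.nodes[row["station_id"]][col] = float(row[col])
        nx.write_graphml(g, path)


def load_network(path: str | Path) -> RiverNetwork:
    """Read a river network edge-list TSV.

    Columns ``child, parent, length_km, subcatchment_area_km2``. A row
    with an empty ``parent`` carries no edge and only assigns the
    subcatchment area of ``child`` (used for the outlet).
    """
    df = pd.read_csv(path, sep="\t", dtype={"child": str, "parent": str})
    required = {"child", "parent", "length_km", "subcatchment_area_km2"}
    missing = required - set(df.columns)
    if missing:
        raise RiverNetworkError(f"{path}: missing column(s) {sorted(missing)}")
    edges = []
    node_areas: dict[str, float] = {}
    for _, row in df.iterrows():
        if pd.isna(row["parent"]) or row["parent"] == "":
            node_areas[row["child"]] = float(row["subcatchment_area_km2"])
        else:
            edges.append(
                (row["child"], row["parent"], float(row["length_km"]), float(row["subcatchment_area_km2"]))
            )
    net = RiverNetwork.from_edges(edges)
    for node, area in node_areas.items():
        if node not in net.graph:
            raise RiverNetworkError(f"{path}: area row for unknown node {node!r}")
        net.graph.nodes[node]["subcatchment_area_km2"] = area
    return net


def write_network(net: RiverNetwork, path: str | Path) -> None:
    rows = []
    for child, parent, data in net.graph.edges(data=True):
        rows.append(
            {
                "child": child,
                "parent": parent,
                "length_km": data["length_km"],
                "subcatchment_area_km2": net.graph.nodes[child]["subcatchment_area_km2"],
            }
        )
    outlet_area = net.graph.nodes[net.outlet]["subcatchment_area_km2"]
    if outlet_area:
        rows.append(
            {"child": net.outlet, "parent": "", "length_km": "", "subcatchment_area_km2": outlet_area}
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def _accumulate(net: RiverNetwork) -> dict[str, tuple[float, float, int]]:
    """Per node: (catchment area, summed leaf-path length, number of leaf paths).

    Processed in topological order so every upstream node is resolved
    first. A headwater contributes one path of length zero at itself.
    """
    g = net.graph
    out: dict[str, tuple[float, float, int]] = {}
    for v in nx.topological_sort(g):
        area = g.nodes[v]["subcatchment_area_km2"]
        total = 0.0
        paths = 0
        for child in g.predecessors(v):
            c_area, c_total, c_paths = out[child]
            area += c_area
            length = g.edges[child, v]["length_km"]
            total += c_total + c_paths * length
            paths += c_paths
        if g.in_degree(v) == 0:
            paths = 1  # the headwater itself, path length 0
        out[v] = (area, total, paths)
    return out


def site_geo_measures(net: RiverNetwork, station: str) -> SiteGeoMeasures:
    """Catchment area and cumulative/mean dendritic distance of one station."""
    if station not in net.graph:
        raise RiverNetworkError(f"unknown station {station!r}")
    area, total, paths = _accumulate(net)[station]
    return SiteGeoMeasures(station, area, total, total / paths, paths)


def all_geo_measures(net: RiverNetwork, stations: Sequence[str] | None = None) -> pd.DataFrame:
    """Measures for every (or the given) station(s), one row each."""
    acc = _accumulate(net)
    if stations is None:
        stations = net.stations
    rows = []
    for st in stations:
        if st not in acc:
            raise RiverNetworkError(f"unknown station {st!r}")
        area, total, paths = acc[st]
        rows.append((st, area, total, total / paths, paths))
    return pd.DataFrame(
        rows,
        columns=[
            "station_id",
            "catchment_area_km2",
            "cumulative_dendritic_km",
            "mean_dendritic_km",
            "n_paths",
        ],
    )


_MEASURE_COLUMNS = {
    "catchment": "catchment_area_km2",
    "cumulative": "cumulative_dendritic_km",
    "mean": "mean_dendritic_km",
}


def pairwise_geo_distance(
    measures: pd.DataFrame,
    which: str = "mean",
    net: RiverNetwork | None = None,
) -> DistanceMatrix:
    """Pairwise geographic distance matrix between stations.

    For ``which`` in {"catchment", "cumulative", "mean"}, the distance is
    the absolute difference of the per-site scalar. ``which="flow"``
    instead measures the along-network path length (km) between the two
    sites through the tree (requires `net`).
    """
    ids = list(measures["station_id"])
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate station in measures")
    if len(ids) < 2:
        raise ValueError("need at least two stations")
    if which == "flow":
        if net is None:
            raise ValueError("which='flow' requires the network")
        und = net.graph.to_undirected(as_view=True)
        mat = np.zeros((len(ids), len(ids)))
        lengths = dict(nx.all_pairs_dijkstra_path_length(und, weight="length_km"))
        for a, sa in enumerate(ids):
            for b, sb in enumerate(ids):
                if a < b:
                    mat[a, b] = mat[b, a] = lengths[sa][sb]
        return DistanceMatrix(mat, ids=ids)
    if which not in _MEASURE_COLUMNS:
        raise ValueError(f"which must be one of {sorted(_MEASURE_COLUMNS)} or 'flow'")
    vals = measures[_MEASURE_COLUMNS[which]].to_numpy(float)
    mat = np.abs(vals[:, None] - vals[None, :])
    return DistanceMatrix(mat, ids=ids)
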