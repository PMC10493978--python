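"""Connected-component analysis (CCA) of perturbation networks.

The sweep removes edges one at a time in ascending magnitude order,
pruning isolated nodes after every removal and counting the connected
components that remain. A single removal can only

* split one component into two (+1) when the edge was a bridge and both
  endpoints keep other edges,
* leave the count unchanged (0) when the edge was inside a cycle, or
* destroy a component (-1) when the edge was its last one.

Reading the trace at magnitude-level granularity (the smallest magnitude
left in the surviving graph) gives the component-count-vs-weight curve.
The *final CC structure* is the surviving graph at the latest (largest
weight) occurrence of the global maximum count: past that point removals
mostly strip whole components, so the structure it captures is the set of
spatially local perturbation clusters. Each component is ranked by its
*vanishing point* — its largest edge magnitude, the removal level at which
it disappears entirely — and by its hop diameter *d*; components with
``d >= 3`` (diameter strictly greater than 2) spread the perturbation far
enough to trace signal-propagation pathways.

Everything in this module is deterministic: ties in magnitude are broken
by lexicographic endpoint labels, and identical graphs give identical
traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import DPCNGraph


@dataclass
class SweepStep:
    """One single-edge removal along the sweep."""

    step: int
    removed_edge: tuple[str, str]
    removed_magnitude: float
    smallest_remaining_magnitude: float  # nan once the graph is empty
    n_components: int
    level_boundary: bool  # last removal of its magnitude tie group


@dataclass
class SweepTrace:
    """Ordered record of the edge-removal sweep.

    ``initial_count`` is the component count before any removal (the state
    at the smallest magnitude level); ``steps`` then record every single
    removal through to the empty graph.
    """

    steps: list[SweepStep]
    initial_count: int
    initial_smallest_magnitude: float
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    s.step,
                    s.removed_edge[0],
                    s.removed_edge[1],
                    s.removed_magnitude,
                    s.smallest_remaining_magnitude,
                    s.n_components,
                    s.level_boundary,
                )
                for s in self.steps
            ],
            columns=[
                "step",
                "removed_u",
                "removed_v",
                "removed_magnitude",
                "smallest_remaining_magnitude",
                "n_components",
                "level_boundary",
            ],
        )

    def level_curve(self) -> pd.DataFrame:
        """Component count as a function of the smallest remaining weight.

        One row per unique magnitude level *w*: the count in the graph that
        keeps exactly the edges with magnitude ``>= w``.
        """
        rows = [(self.initial_smallest_magnitude, self.initial_count)]
        for s in self.steps:
            if s.level_boundary and not math.isnan(s.smallest_remaining_magnitude):
                rows.append((s.smallest_remaining_magnitude, s.n_components))
        return pd.DataFrame(rows, columns=["weight", "n_components"])


def _removal_order(dpcn: DPCNGraph) -> list[tuple[float, tuple[str, str]]]:
    edges = [
        (d["magnitude"], tuple(sorted((u, v))))
        for u, v, d in dpcn.graph.edges(data=True)
    ]
    edges.sort()
    return edges


def sweep(dpcn: DPCNGraph) -> SweepTrace:
    """Run the full edge-removal sweep down to the empty graph.

    Edges leave in ascending magnitude, ties broken by sorted endpoint
    labels; after each removal degree-0 nodes are pruned (and never
    return), and components are counted by breadth-first search.
    """
    if dpcn.n_edges == 0:
        raise ValueError("cannot sweep an empty graph")
    g = dpcn.graph.copy()
    g.remove_nodes_from([n for n in g.nodes if g.degree(n) == 0])
    order = _removal_order(dpcn)
    steps: list[SweepStep] = []
    initial_count = nx.number_connected_components(g)
    for i, (mag, (u, v)) in enumerate(order):
        g.remove_edge(u, v)
        for node in (u, v):
            if g.degree(node) == 0:
                g.remove_node(node)
        remaining = order[i + 1][0] if i + 1 < len(order) else math.nan
        steps.append(
            SweepStep(
                step=i,
                removed_edge=(u, v),
                removed_magnitude=mag,
                smallest_remaining_magnitude=remaining,
                n_components=nx.number_connected_components(g),
                level_boundary=(i + 1 == len(order)) or (order[i + 1][0] > mag),
            )
        )
    return SweepTrace(
        steps=steps,
        initial_count=initial_count,
        initial_smallest_magnitude=order[0][0],
        provenance=dict(dpcn.metadata),
    )


@dataclass
class ComponentRecord:
    """One connected component of the surviving graph."""

    nodes: frozenset
    edges: list[tuple[str, str, float]]  # (u, v, magnitude), u < v
    order: int  # node count
    size: int  # edge count
    diameter: int  # max hop distance
    vanishing_point: float  # largest edge magnitude

    def subgraph(self) -> nx.Graph:
        g = nx.Graph()
        for u, v, m in self.edges:
            g.add_edge(u, v, magnitude=m)
        return g


def _component_record(g: nx.Graph, nodes) -> ComponentRecord:
    sub = g.subgraph(nodes)
    edges = sorted(
        (min(u, v), max(u, v), float(d["magnitude"]))
        for u, v, d in sub.edges(data=True)
    )
    return ComponentRecord(
        nodes=frozenset(nodes),
        edges=edges,
        order=sub.number_of_nodes(),
        size=sub.number_of_edges(),
        diameter=diameter_of(sub),
        vanishing_point=max(m for _, _, m in edges),
    )


def diameter_of(component) -> int:
    """Hop-count diameter: the largest shortest-path length (in edges)
    between any pair of nodes. Edge weights are ignored."""
    if isinstance(component, ComponentRecord):
        component = component.subgraph()
    if not nx.is_connected(component):
        raise ValueError("diameter is defined only for connected components")
    return int(nx.diameter(component))


def vanishing_point_of(component) -> float:
    """Largest edge magnitude in the component — the removal level at which
    its last edge (and so the whole component) disappears."""
    if isinstance(component, ComponentRecord):
        return component.vanishing_point
    mags = [d["magnitude"] for _, _, d in component.edges(data=True)]
    if not mags:
        raise ValueError("component has no edges")
    return float(max(mags))


@dataclass
class FinalStructure:
    """The component set at the latest occurrence of the maximum count."""

    components: list[ComponentRecord]
    critical_weight: float  # smallest magnitude in the surviving graph
    max_count: int

    def vanishing_points(self) -> np.ndarray:
        return np.array([c.vanishing_point for c in self.components])


def _graph_at_level(dpcn: DPCNGraph, level: float) -> nx.Graph:
    g = nx.Graph()
    for u, v, d in dpcn.graph.edges(data=True):
        if d["magnitude"] >= level:
            g.add_edge(u, v, **d)
    return g


def final_structure(trace: SweepTrace, dpcn: DPCNGraph) -> FinalStructure:
    """Locate the final CC structure on a sweep trace.

    The count curve is read at magnitude-level granularity (level *w* =
    the graph keeping edges with magnitude ``>= w``, i.e. the state after
    a whole tie group has been removed). The structure is taken at the
    largest level attaining the global maximum count, and its components
    are returned with diameters and vanishing points filled in.
    """
    curve = trace.level_curve()
    max_count = int(curve["n_components"].max())
    at_max = curve[curve["n_components"] == max_count]
    critical = float(at_max["weight"].max())
    g = _graph_at_level(dpcn, critical)
    comps = [
        _component_record(g, nodes) for nodes in nx.connected_components(g)
    ]
    comps.sort(key=lambda c: (-c.vanishing_point, sorted(c.nodes)))
    return FinalStructure(components=comps, critical_weight=critical, max_count=max_count)


def select_major(
    final: FinalStructure, d_min: int = 3
) -> list[ComponentRecord]:
    """Components whose diameter reaches ``d_min`` (default 3, i.e. the
    strict ``d > 2`` rule), sorted by vanishing point descending.

    These are the components across which the contact perturbation spreads
    over a sizable span — the pathway candidates.
    """
    if d_min < 1:
        raise ValueError(f"d_min must be >= 1, got {d_min}")
    selected = [c for c in final.components if c.diameter >= d_min]
    selected.sort(key=lambda c: (-c.vanishing_point, sorted(c.nodes)))
    return selected


def vanishing_distribution(final: FinalStructure) -> dict:
    """Median and quartiles of the vanishing points, plus the
    per-component table (box-plot summary of component strengths)."""
    if not final.components:
        raise ValueError("final structure has no components")
    vp = final.vanishing_points()
    table = pd.DataFrame(
        {
            "component": range(len(final.components)),
            "order": [c.order for c in final.components],
            "size": [c.size for c in final.components],
            "diameter": [c.diameter for c in final.components],
            "vanishing_point": vp,
        }
    )
    return {
        "median": float(np.median(vp)),
        "q1": float(np.percentile(vp, 25)),
        "q3": float(np.percentile(vp, 75)),
        "n_components": len(vp),
        "table": table,
    }


def run_cca(dpcn: DPCNGraph, d_min: int = 3):
    """Convenience wrapper: sweep, final structure, major components."""
    trace = sweep(dpcn)
    final = final_structure(trace, dpcn)
    major = select_major(final, d_min=d_min)
    return trace, final, major
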