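"""Signed perturbation networks from pairs of residue contact matrices.

The dynamical perturbation contact network (DPCN) is the graph whose
adjacency matrix is the difference of two average residue contact matrices,
one per simulated state. Edge weights are signed (final minus initial mean
atomic contacts): positive weights mean more contacts in the perturbed
state (rendered red), negative weights more contacts in the initial state
(rendered blue). All thresholding and component analysis downstream uses
the magnitude |weight|; the sign only encodes direction of change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import networkx as nx
import numpy as np
import pandas as pd

from .contacts import AverageResidueContactMatrix


@dataclass
class DPCNGraph:
    """Residue-node graph with signed perturbation edge weights.

    Wraps a :class:`networkx.Graph` whose nodes are ``chain:resseq:resname``
    labels and whose edges carry ``weight`` (signed), ``magnitude``
    (``|weight|``) and ``sign`` attributes. Invariants: no self-loops, no
    zero-weight edges.
    """

    graph: nx.Graph
    metadata: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges_table(self) -> pd.DataFrame:
        """Long-form edge table sorted by endpoint labels (deterministic)."""
        rows = []
        for u, v, d in self.graph.edges(data=True):
            a, b = sorted((u, v))
            rows.append((a, b, d["weight"], d["magnitude"]))
        rows.sort()
        return pd.DataFrame(rows, columns=["node_u", "node_v", "weight", "magnitude"])

    def magnitudes(self) -> np.ndarray:
        return np.array(
            [d["magnitude"] for _, _, d in self.graph.edges(data=True)], dtype=float
        )


def dpcn_from_edges(edges, metadata=None) -> DPCNGraph:
    """Build a :class:`DPCNGraph` from ``(u, v, signed_weight)`` triples."""
    g = nx.Graph()
    for u, v, w in edges:
        if u == v:
            raise ValueError(f"self-loop on node {u!r}")
        if w == 0:
            raise ValueError(f"zero-weight edge {u!r} -- {v!r}")
        g.add_edge(u, v, weight=float(w), magnitude=abs(float(w)),
                   sign=1 if w > 0 else -1)
    return DPCNGraph(g, metadata or {})


_make_edge_graph = dpcn_from_edges


def build_dpcn(
    r_initial: AverageResidueContactMatrix,
    r_final: AverageResidueContactMatrix,
    epsilon: float = 0.0,
) -> DPCNGraph:
    """Perturbation network: ``R_final - R_initial`` as a weighted graph.

    An edge is stored for every residue pair whose mean contact count
    changed by more than ``epsilon`` in absolute value (default 0: any
    nonzero difference). Residue label sets must match exactly.
    """
    if r_initial.residue_labels != r_final.residue_labels:
        a, b = set(r_initial.residue_labels), set(r_final.residue_labels)
        raise ValueError(
            "residue label mismatch between the two states; "
            f"only-initial={sorted(a - b)}, only-final={sorted(b - a)}"
        )
    diff = r_final.entries - r_initial.entries
    labels = r_initial.residue_labels
    edges = []
    iu, ju = np.triu_indices(len(labels), k=1)
    for i, j in zip(iu, ju):
        w = diff[i, j]
        if abs(w) > epsilon:
            edges.append((labels[i], labels[j], w))
    meta = {
        "initial": r_initial.selection_description,
        "final": r_final.selection_description,
        "cutoff": r_initial.cutoff,
        "epsilon": epsilon,
    }
    return _make_edge_graph(edges, meta)


def top_k_edges(dpcn: DPCNGraph, k: int) -> tuple[DPCNGraph, bool]:
    """Brute-force baseline: subgraph of the ``k`` largest-magnitude edges.

    When ties straddle rank ``k`` every tied edge is kept (the subgraph may
    then exceed ``k`` edges); the returned flag reports whether that
    happened. ``k >= |E|`` returns the whole graph.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    edges = [
        (d["magnitude"], tuple(sorted((u, v))), u, v, d["weight"])
        for u, v, d in dpcn.graph.edges(data=True)
    ]
    if k >= len(edges):
        return _make_edge_graph(
            [(u, v, w) for _, _, u, v, w in edges], dict(dpcn.metadata)
        ), False
    edges.sort(key=lambda e: (-e[0], e[1]))
    threshold = edges[k - 1][0]
    kept = [e for e in edges if e[0] >= threshold]
    tie = len(kept) > k
    return _make_edge_graph(
        [(u, v, w) for _, _, u, v, w in kept], dict(dpcn.metadata)
    ), tie


def magnitude_decay(dpcn: DPCNGraph) -> pd.DataFrame:
    """Edge count surviving each magnitude threshold.

    Thresholds are the sorted unique magnitudes; the count at threshold *t*
    is the number of edges with magnitude ``>= t`` (non-increasing in *t*).
    """
    mags = np.sort(dpcn.magnitudes())
    if len(mags) == 0:
        return pd.DataFrame(columns=["threshold", "n_edges"])
    uniq = np.unique(mags)
    counts = len(mags) - np.searchsorted(mags, uniq, side="left")
    return pd.DataFrame({"threshold": uniq, "n_edges": counts.astype(int)})


def filter_edges(
    dpcn: DPCNGraph, predicate: Callable[[str], bool]
) -> DPCNGraph:
    """Subgraph induced by edges whose both endpoints satisfy ``predicate``.

    This is a residue-level filter (e.g. hydrophobic residues only). For
    atom-class subgraphs such as backbone-only contacts, re-project from the
    atomic matrices with the corresponding atom selection instead — the
    backbone contact network is not a subgraph of the heavy-atom one.
    """
    keep = {}
    for node in dpcn.graph.nodes:
        try:
            keep[node] = bool(predicate(node))
        except Exception as exc:  # predicate must be total over nodes
            raise ValueError(f"predicate undefined for node {node!r}: {exc}") from exc
    edges = [
        (u, v, d["weight"])
        for u, v, d in dpcn.graph.edges(data=True)
        if keep[u] and keep[v]
    ]
    return _make_edge_graph(edges, dict(dpcn.metadata))


HYDROPHOBIC_RESNAMES = frozenset(
    ["ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP", "GLY", "CYS"]
)


def hydrophobic_predicate(node: str) -> bool:
    """True when a ``chain:resseq:resname`` node is a hydrophobic residue."""
    resname = node.rsplit(":", 1)[-1].upper()
    return resname in HYDROPHOBIC_RESNAMES
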