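"""Synthetic fixtures with known ground truth.

Two generators make every stage of the pipeline testable without real MD
data:

* :func:`make_two_state_trajectories` builds a pair of toy trajectory
  ensembles (an "initial" and a "perturbed" state) in which chosen residue
  pairs change their contact frequency by an exactly planted amount, so the
  perturbation-network edge weights the pipeline should recover are known
  rationals with zero tolerance;
* :func:`make_planted_graph` builds weighted graphs whose component
  structure under the edge-removal sweep is known by construction (cluster
  internal magnitudes strictly above all bridge magnitudes).

Geometry of the toy trajectories: pseudo-residues are beads strung along a
straight chain with 20 Angstrom spacing — far beyond the 5 Angstrom contact
cutoff, so no contacts exist between residues except the planted ones. A
planted pair (p, q) is realized by ``m`` anchor atoms on residue p and one
probe atom owned by residue q that toggles its radial distance from the
anchors between 4.5 Angstrom (contact) and 6.5 Angstrom (no contact), both
far from the cutoff boundary. Frame counts are integers, so frame-averaged
contact frequencies are exact rationals and the planted weights are
recovered with zero floating-point error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

import networkx as nx

from .contacts import ATOM_TABLE_COLUMNS, FrameEnsemble
from .network import DPCNGraph, _make_edge_graph

_SPACING = 20.0  # chain spacing, Angstrom; > cutoff + max probe reach
_R_CONTACT = 4.5  # probe radius in contact frames
_R_APART = 6.5  # probe radius in non-contact frames
_ANCHOR_GROUP_SPACING = 4.0  # between anchor groups on one residue
_ANCHOR_ATOM_SPACING = 0.3  # between anchor atoms within a group
_MAX_GROUPS_PER_RESIDUE = 3
_RESNAMES = ["ALA", "GLY", "LEU", "SER", "VAL", "THR", "LYS", "ASP", "PHE", "ILE"]


@dataclass
class PerturbationSpec:
    """Planted contact-frequency changes between two states.

    ``pairs[k] = (p, q)`` plants a change on residue ordinals p and q;
    ``deltas[k]`` is the contact-frequency change (perturbed minus initial,
    in [-1, 1]); ``n_atom_pairs[k]`` is how many atomic contacts toggle
    together, so the planted network edge weight is ``deltas[k] *
    n_atom_pairs[k]``. ``base_frequency`` is the initial-state contact
    frequency. ``delta * n_frames`` and ``base_frequency * n_frames`` must
    be integers so the planted weights are exact.
    """

    n_residues: int
    pairs: list[tuple[int, int]]
    deltas: list[float]
    n_atom_pairs: list[int]
    n_frames: int
    base_frequency: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len({tuple(sorted(p)) for p in self.pairs}) != len(self.pairs):
            raise ValueError("affected residue pairs must be distinct")
        if len(self.deltas) != len(self.pairs) or len(self.n_atom_pairs) != len(self.pairs):
            raise ValueError("pairs, deltas and n_atom_pairs must have equal length")
        if self.n_frames < 1:
            raise ValueError("need at least one frame per state")
        for name, value in [("base_frequency", self.base_frequency)] + [
            (f"delta[{k}]", d) for k, d in enumerate(self.deltas)
        ]:
            if abs(value * self.n_frames - round(value * self.n_frames)) > 1e-9:
                raise ValueError(
                    f"{name} * n_frames = {value * self.n_frames} is not an "
                    "integer; planted weights would not be exact"
                )
        for k, d in enumerate(self.deltas):
            lo, hi = self.base_frequency, self.base_frequency + d
            if not (0 <= lo <= 1 and 0 <= hi <= 1):
                raise ValueError(
                    f"pair {k}: frequencies ({lo}, {hi}) outside [0, 1]"
                )
        for p, q in self.pairs:
            if p == q or not (0 <= p < self.n_residues and 0 <= q < self.n_residues):
                raise ValueError(f"invalid residue pair ({p}, {q})")
        if any(m < 1 or m > 3 for m in self.n_atom_pairs):
            raise ValueError("n_atom_pairs must be in 1..3 (anchor group size)")

    def planted_weights(self) -> dict[tuple[int, int], float]:
        """Expected perturbation-network weight per planted residue pair.

        Computed from the integer frame counts, exactly as the pipeline's
        frame averaging produces it, so the comparison can be exact.
        """
        f = self.n_frames
        k0 = round(self.base_frequency * f)
        out = {}
        for p, d, m in zip(self.pairs, self.deltas, self.n_atom_pairs):
            k1 = round((self.base_frequency + d) * f)
            w = m * (k1 - k0) / f
            if w != 0:
                out[tuple(sorted(p))] = w
        return out


def _layout(spec: PerturbationSpec):
    """Static atom layout: per-atom metadata plus anchor/probe geometry."""
    records = []  # atom_table rows
    base_pos = []  # position ignoring probe toggling
    ca_index = {}
    for r in range(spec.n_residues):
        records.append(("CA", "C", r, _RESNAMES[r % len(_RESNAMES)], r + 1, "A"))
        base_pos.append(np.array([_SPACING * r, 0.0, 0.0]))
        ca_index[r] = len(records) - 1

    groups_at = {r: 0 for r in range(spec.n_residues)}
    plan = []  # per pair: (probe_atom_index, anchor_centroid, direction)
    for k, ((p, q), m) in enumerate(zip(spec.pairs, spec.n_atom_pairs)):
        g = groups_at[p]
        if g >= _MAX_GROUPS_PER_RESIDUE:
            raise ValueError(
                f"infeasible geometry: residue {p} anchors more than "
                f"{_MAX_GROUPS_PER_RESIDUE} planted pairs"
            )
        groups_at[p] = g + 1
        x0 = _SPACING * p + _ANCHOR_GROUP_SPACING * g
        # group 0 reuses the CA as its first anchor
        start_j = 1 if g == 0 else 0
        for j in range(start_j, m):
            records.append(
                (f"A{k}{j}", "C", p, _RESNAMES[p % len(_RESNAMES)], p + 1, "A")
            )
            base_pos.append(np.array([x0 + _ANCHOR_ATOM_SPACING * j, 0.0, 0.0]))
        centroid = np.array(
            [x0 + _ANCHOR_ATOM_SPACING * (m - 1) / 2.0, 0.0, 0.0]
        )
        direction = np.array([0.0, 1.0 if g % 2 == 0 else -1.0, 0.0])
        records.append(
            (f"P{k}", "C", q, _RESNAMES[q % len(_RESNAMES)], q + 1, "A")
        )
        base_pos.append(centroid + _R_APART * direction)
        plan.append((len(records) - 1, centroid, direction))
    table = pd.DataFrame(records, columns=ATOM_TABLE_COLUMNS)
    return table, np.array(base_pos), plan


def _contact_frames(rng: np.random.Generator, n_frames: int, k: int) -> np.ndarray:
    mask = np.zeros(n_frames, dtype=bool)
    mask[rng.choice(n_frames, size=k, replace=False)] = True
    return mask


def make_two_state_trajectories(
    spec: PerturbationSpec,
) -> tuple[FrameEnsemble, FrameEnsemble]:
    """Build the (initial, perturbed) toy ensembles for a perturbation spec.

    In the initial state each planted pair is in contact in exactly
    ``base_frequency * n_frames`` frames; in the perturbed state in
    ``(base_frequency + delta) * n_frames`` frames. All other pairs have
    identical contact states (none) in both states.
    """
    table, base_pos, plan = _layout(spec)
    rng = np.random.default_rng(spec.seed)
    ensembles = []
    for state_idx, shift in enumerate([0.0, 1.0]):
        coords = np.repeat(base_pos[None, :, :], spec.n_frames, axis=0)
        for (probe_idx, centroid, direction), delta in zip(plan, spec.deltas):
            freq = spec.base_frequency + (delta if state_idx == 1 else 0.0)
            k = int(round(freq * spec.n_frames))
            contact = _contact_frames(rng, spec.n_frames, k)
            radii = np.where(contact, _R_CONTACT, _R_APART)
            coords[:, probe_idx, :] = centroid + radii[:, None] * direction
        name = "initial" if state_idx == 0 else "perturbed"
        ensembles.append(
            FrameEnsemble(
                coords,
                table.copy(),
                [(f"synthetic:{name}", i) for i in range(spec.n_frames)],
            )
        )
    return ensembles[0], ensembles[1]


# ---------------------------------------------------------------------------
# planted-component graphs


@dataclass
class PlantedGraphSpec:
    """Weighted graph with planted component structure.

    Each cluster is internally wired at a single magnitude level drawn
    from ``internal_range`` (one draw per cluster, shared by all its
    edges); bridges joining consecutive clusters use ``bridge_range``.
    With ``min(internal_range) > max(bridge_range)`` the sweep's final
    structure provably equals the planted clusters: below the smallest
    cluster level only bridges are removed, so the count peaks at exactly
    the cluster number with every cluster intact, and above it whole
    clusters vanish in one magnitude level each, so the count only falls.
    (Per-edge random internal magnitudes would not give this guarantee —
    removals inside a path-like cluster split it and push the count past
    the planted number.)
    """

    clusters: list[tuple[int, str]]  # (n_nodes, topology)
    internal_range: tuple[float, float] = (5.0, 8.0)
    bridge_range: tuple[float, float] = (0.5, 2.0)
    bridges: list[tuple[int, int]] | None = None  # cluster index pairs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.internal_range[0] <= self.bridge_range[1]:
            raise ValueError(
                "separation violated: min internal magnitude "
                f"{self.internal_range[0]} must exceed max bridge magnitude "
                f"{self.bridge_range[1]}"
            )
        for n, topo in self.clusters:
            if topo not in ("path", "cycle", "star", "random"):
                raise ValueError(f"unknown topology {topo!r}")
            if n < 2 or (topo == "cycle" and n < 3):
                raise ValueError(f"cluster ({n}, {topo}) too small")
        if self.bridges is None:
            self.bridges = [(i, i + 1) for i in range(len(self.clusters) - 1)]

    @property
    def separation_factor(self) -> float:
        return self.internal_range[0] / self.bridge_range[1]


def analytic_diameter(n: int, topology: str) -> int | None:
    """Known hop diameter of the planted topologies (None for random)."""
    if topology == "path":
        return n - 1
    if topology == "cycle":
        return n // 2
    if topology == "star":
        return 1 if n == 2 else 2
    return None


def _cluster_edges(n: int, topology: str, rng: np.random.Generator):
    if topology == "path":
        return [(i, i + 1) for i in range(n - 1)]
    if topology == "cycle":
        return [(i, (i + 1) % n) for i in range(n)]
    if topology == "star":
        return [(0, i) for i in range(1, n)]
    # random connected: random spanning tree plus a few extra edges
    edges = [(int(rng.integers(0, i)), i) for i in range(1, n)]
    extra = int(rng.integers(0, n))
    seen = {tuple(sorted(e)) for e in edges}
    for _ in range(extra):
        i, j = rng.integers(0, n, size=2)
        if i != j and tuple(sorted((int(i), int(j)))) not in seen:
            seen.add(tuple(sorted((int(i), int(j)))))
            edges.append((int(min(i, j)), int(max(i, j))))
    return edges


def make_planted_graph(
    spec: PlantedGraphSpec,
) -> tuple[DPCNGraph, dict]:
    """Build the planted graph and its ground truth.

    Returns the graph plus a dict with per-cluster node sets, topologies and
    analytic diameters, and the separation factor actually achieved.
    """
    rng = np.random.default_rng(spec.seed)
    g_edges = []
    clusters_truth = []
    node_offset = 0
    cluster_nodes = []

    def label(i: int) -> str:
        return f"A:{i + 1}:{_RESNAMES[i % len(_RESNAMES)]}"

    for n, topo in spec.clusters:
        nodes = [label(node_offset + i) for i in range(n)]
        level = rng.uniform(*spec.internal_range)  # one level per cluster
        for i, j in _cluster_edges(n, topo, rng):
            sign = 1 if rng.random() < 0.5 else -1
            g_edges.append((nodes[i], nodes[j], sign * level))
        clusters_truth.append(
            {
                "nodes": frozenset(nodes),
                "topology": topo,
                "magnitude_level": level,
                "analytic_diameter": analytic_diameter(n, topo),
            }
        )
        cluster_nodes.append(nodes)
        node_offset += n
    for ci, cj in spec.bridges:
        u = cluster_nodes[ci][int(rng.integers(len(cluster_nodes[ci])))]
        v = cluster_nodes[cj][int(rng.integers(len(cluster_nodes[cj])))]
        mag = rng.uniform(*spec.bridge_range)
        sign = 1 if rng.random() < 0.5 else -1
        g_edges.append((u, v, sign * mag))
    graph = _make_edge_graph(g_edges, {"generator": "planted", "seed": spec.seed})
    truth = {
        "clusters": clusters_truth,
        "n_clusters": len(clusters_truth),
        "separation_factor": spec.separation_factor,
    }
    return graph, truth


def random_dpcn(
    n_nodes: int = 60,
    n_edges: int = 200,
    seed: int = 0,
    magnitude_range: tuple[float, float] = (0.05, 8.0),
) -> DPCNGraph:
    """Unstructured random weighted graph (for oracle-style tests)."""
    rng = np.random.default_rng(seed)
    labels = [f"A:{i + 1}:{_RESNAMES[i % len(_RESNAMES)]}" for i in range(n_nodes)]
    chosen = set()
    while len(chosen) < n_edges:
        i, j = rng.integers(0, n_nodes, size=2)
        if i != j:
            chosen.add((int(min(i, j)), int(max(i, j))))
    edges = []
    for i, j in sorted(chosen):
        mag = rng.uniform(*magnitude_range)
        sign = 1 if rng.random() < 0.5 else -1
        edges.append((labels[i], labels[j], sign * mag))
    return _make_edge_graph(edges, {"generator": "random", "seed": seed})
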