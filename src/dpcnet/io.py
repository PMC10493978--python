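"""Readers and writers for every on-disk artifact.

Trajectories come in through MDTraj (PDB topology; DCD, XTC or multi-model
PDB coordinates; coordinates normalized to Angstrom). Everything the
pipeline produces goes out as plain text: residue contact matrices as TSV
(dense) or CSV (long-form edge table), perturbation graphs as GraphML or
edge CSV, sweep traces as CSV, final component structures as JSON, and a
PyMOL script for 3D rendering. Every artifact carries a provenance header
and all writers are deterministic given their inputs (stable residue-label
ordering), so re-runs are byte-identical apart from the timestamp field.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import mdtraj as md
import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .contacts import ATOM_TABLE_COLUMNS, AverageResidueContactMatrix, FrameEnsemble
from .components import ComponentRecord, FinalStructure, SweepTrace, SweepStep
from .network import DPCNGraph

_FLOAT_FMT = "%.12g"  # 12 significant digits for text round-trips


@dataclass
class ProvenanceHeader:
    """Metadata stamped on every written artifact; round-trips losslessly."""

    tool_version: str = __version__
    input_hashes: dict = field(default_factory=dict)
    cutoff: float | None = None
    selection: str | None = None
    frame_counts: dict = field(default_factory=dict)
    timestamp: str | None = None
    seed: int | None = None

    def to_lines(self) -> list[str]:
        payload = {k: v for k, v in asdict(self).items() if v not in (None, {}, [])}
        return ["# provenance: " + json.dumps(payload, sort_keys=True)]

    @classmethod
    def from_lines(cls, lines: list[str]) -> "ProvenanceHeader":
        for line in lines:
            if line.startswith("# provenance: "):
                return cls(**json.loads(line[len("# provenance: "):]))
        return cls(tool_version="unknown")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# trajectories


def read_trajectory(topology: str | Path, *coordinates: str | Path) -> FrameEnsemble:
    """Load a trajectory ensemble into a :class:`FrameEnsemble`.

    ``topology`` is a PDB file; ``coordinates`` are zero or more DCD, XTC
    or (multi-model) PDB files, pooled frame-major with equal weight per
    frame. With no coordinate files the topology's own models are the
    frames. Coordinates are converted to Angstrom.
    """
    topology = Path(topology)
    if not topology.exists():
        raise FileNotFoundError(f"topology file not found: {topology}")
    top = md.load_topology(str(topology))
    sources = [Path(c) for c in coordinates] if coordinates else [topology]
    frames, provenance = [], []
    for src in sources:
        if not src.exists():
            raise FileNotFoundError(f"coordinate file not found: {src}")
        try:
            traj = md.load(str(src), top=top)
        except Exception as exc:
            raise ValueError(f"unreadable trajectory file {src}: {exc}") from exc
        if traj.n_atoms != top.n_atoms:
            raise ValueError(
                f"atom count mismatch: topology has {top.n_atoms} atoms, "
                f"{src} has {traj.n_atoms}"
            )
        frames.append(traj.xyz * 10.0)  # nm -> Angstrom
        provenance.extend((str(src), i) for i in range(traj.n_frames))
    coords = np.concatenate(frames, axis=0)
    rows = []
    for atom in top.atoms:
        rows.append(
            (
                atom.name,
                atom.element.symbol if atom.element is not None else "",
                atom.residue.index,
                atom.residue.name,
                atom.residue.resSeq,
                atom.residue.chain.chain_id or "A",
            )
        )
    table = pd.DataFrame(rows, columns=ATOM_TABLE_COLUMNS)
    return FrameEnsemble(coords, table, provenance)


def write_ensemble_pdb(ensemble: FrameEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB (one MODEL per frame)."""
    # group atoms by residue (stable) so PDB readers keep residues whole
    order = np.argsort(
        ensemble.atom_table["residue_index"].to_numpy(), kind="stable"
    )
    table = ensemble.atom_table.iloc[order]
    coords = ensemble.coordinates[:, order, :]
    top = md.Topology()
    chains: dict[str, object] = {}
    residues: dict[int, object] = {}
    for row in table.itertuples():
        if row.chain not in chains:
            chains[row.chain] = top.add_chain(chain_id=str(row.chain))
        if row.residue_index not in residues:
            residues[row.residue_index] = top.add_residue(
                row.resname, chains[row.chain], resSeq=int(row.resseq)
            )
        element = md.element.get_by_symbol(row.element) if row.element else None
        top.add_atom(row.name, element, residues[row.residue_index])
    traj = md.Trajectory(coords / 10.0, top)  # Angstrom -> nm
    traj.save_pdb(str(path))


# ---------------------------------------------------------------------------
# residue contact matrices


def write_matrix(
    matrix: AverageResidueContactMatrix,
    path: str | Path,
    provenance: ProvenanceHeader | None = None,
) -> None:
    """Dense TSV with residue-label header and provenance comment lines."""
    prov = provenance or ProvenanceHeader(
        cutoff=matrix.cutoff,
        selection=matrix.selection_description,
        frame_counts={"n_frames": matrix.n_frames},
    )
    with open(path, "w") as fh:
        for line in prov.to_lines():
            fh.write(line + "\n")
        fh.write("# n_frames: %d\n" % matrix.n_frames)
        fh.write("label\t" + "\t".join(matrix.residue_labels) + "\n")
        for label, row in zip(matrix.residue_labels, matrix.entries):
            fh.write(label + "\t" + "\t".join(_FLOAT_FMT % v for v in row) + "\n")


def read_matrix(path: str | Path) -> AverageResidueContactMatrix:
    header_lines, n_frames = [], 1
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            header_lines.append(line.rstrip("\n"))
            if line.startswith("# n_frames:"):
                n_frames = int(line.split(":", 1)[1])
        else:
            body.append(line.rstrip("\n"))
    if not body:
        raise ValueError(f"no matrix body in {path}")
    labels = body[0].split("\t")[1:]
    rows = []
    for line in body[1:]:
        parts = line.split("\t")
        rows.append([float(v) for v in parts[1:]])
    entries = np.array(rows)
    if entries.shape != (len(labels), len(labels)):
        raise ValueError(
            f"matrix shape {entries.shape} does not match {len(labels)} labels"
        )
    prov = ProvenanceHeader.from_lines(header_lines)
    return AverageResidueContactMatrix(
        entries,
        labels,
        n_frames,
        cutoff=prov.cutoff if prov.cutoff is not None else 5.0,
        selection_description=prov.selection or "",
    )


def write_matrix_edge_table(
    matrix: AverageResidueContactMatrix, path: str | Path
) -> None:
    """Long-form nonzero entries: chain_p, resid_p, chain_q, resid_q, weight."""
    rows = []
    labels = matrix.residue_labels
    for i in range(matrix.n_residues):
        for j in range(i + 1, matrix.n_residues):
            w = matrix.entries[i, j]
            if w != 0:
                cp, rp, _ = labels[i].split(":")
                cq, rq, _ = labels[j].split(":")
                rows.append((cp, int(rp), cq, int(rq), w))
    pd.DataFrame(
        rows, columns=["chain_p", "resid_p", "chain_q", "resid_q", "weight"]
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# perturbation graphs


def write_graph_graphml(dpcn: DPCNGraph, path: str | Path) -> None:
    g = nx.Graph()
    for u, v, d in sorted(
        dpcn.graph.edges(data=True), key=lambda e: tuple(sorted(e[:2]))
    ):
        g.add_edge(u, v, weight=d["weight"], magnitude=d["magnitude"], sign=d["sign"])
    nx.write_graphml(g, str(path))


def read_graph_graphml(path: str | Path) -> DPCNGraph:
    g = nx.read_graphml(str(path))
    out = nx.Graph()
    for u, v, d in g.edges(data=True):
        out.add_edge(
            u,
            v,
            weight=float(d["weight"]),
            magnitude=float(d["magnitude"]),
            sign=int(d["sign"]),
        )
    return DPCNGraph(out, {"source": str(path)})


def write_graph_csv(
    dpcn: DPCNGraph, path: str | Path, provenance: ProvenanceHeader | None = None
) -> None:
    """Edge list CSV: chain/resid/resname per endpoint, weight, magnitude."""
    rows = []
    for u, v, d in dpcn.graph.edges(data=True):
        a, b = sorted((u, v))
        ca, ra, na = a.split(":")
        cb, rb, nb = b.split(":")
        rows.append((ca, int(ra), na, cb, int(rb), nb, d["weight"], d["magnitude"]))
    rows.sort()
    frame = pd.DataFrame(
        rows,
        columns=[
            "chain_p", "resid_p", "resname_p",
            "chain_q", "resid_q", "resname_q",
            "weight", "magnitude",
        ],
    )
    with open(path, "w") as fh:
        for line in (provenance or ProvenanceHeader()).to_lines():
            fh.write(line + "\n")
        frame.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_graph_csv(path: str | Path) -> DPCNGraph:
    frame = pd.read_csv(path, comment="#")
    required = {"chain_p", "resid_p", "resname_p", "chain_q", "resid_q", "resname_q", "weight"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"edge CSV missing columns: {sorted(missing)}")
    g = nx.Graph()
    seen = set()
    for row in frame.itertuples():
        u = f"{row.chain_p}:{row.resid_p}:{row.resname_p}"
        v = f"{row.chain_q}:{row.resid_q}:{row.resname_q}"
        key = tuple(sorted((u, v)))
        if key in seen:
            raise ValueError(f"duplicate edge row for {key[0]} -- {key[1]}")
        seen.add(key)
        w = float(row.weight)
        g.add_edge(u, v, weight=w, magnitude=abs(w), sign=1 if w > 0 else -1)
    return DPCNGraph(g, {"source": str(path)})


# ---------------------------------------------------------------------------
# sweep traces and final structures


def write_trace(
    trace: SweepTrace, path: str | Path, provenance: ProvenanceHeader | None = None
) -> None:
    with open(path, "w") as fh:
        for line in (provenance or ProvenanceHeader()).to_lines():
            fh.write(line + "\n")
        fh.write(
            "# initial: %s\n"
            % json.dumps(
                {
                    "n_components": trace.initial_count,
                    "smallest_magnitude": trace.initial_smallest_magnitude,
                }
            )
        )
        trace.to_frame().to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_trace(path: str | Path) -> SweepTrace:
    initial = None
    with open(path) as fh:
        lines = fh.readlines()
    header = [l for l in lines if l.startswith("#")]
    for line in header:
        if line.startswith("# initial: "):
            initial = json.loads(line[len("# initial: "):])
    if initial is None:
        raise ValueError(f"trace file {path} lacks the 'initial' header field")
    from io import StringIO

    frame = pd.read_csv(StringIO("".join(l for l in lines if not l.startswith("#"))))
    steps = [
        SweepStep(
            step=int(r.step),
            removed_edge=(r.removed_u, r.removed_v),
            removed_magnitude=float(r.removed_magnitude),
            smallest_remaining_magnitude=float(r.smallest_remaining_magnitude)
            if not pd.isna(r.smallest_remaining_magnitude)
            else math.nan,
            n_components=int(r.n_components),
            level_boundary=bool(r.level_boundary),
        )
        for r in frame.itertuples()
    ]
    return SweepTrace(
        steps=steps,
        initial_count=int(initial["n_components"]),
        initial_smallest_magnitude=float(initial["smallest_magnitude"]),
    )


def write_final_structure(
    final: FinalStructure, path: str | Path, provenance: ProvenanceHeader | None = None
) -> None:
    payload = {
        "provenance": json.loads(
            (provenance or ProvenanceHeader()).to_lines()[0][len("# provenance: "):]
        ),
        "critical_weight": final.critical_weight,
        "max_count": final.max_count,
        "components": [
            {
                "nodes": sorted(c.nodes),
                "edges": [[u, v, m] for u, v, m in c.edges],
                "order": c.order,
                "size": c.size,
                "diameter": c.diameter,
                "vanishing_point": c.vanishing_point,
            }
            for c in final.components
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_final_structure(path: str | Path) -> FinalStructure:
    with open(path) as fh:
        payload = json.load(fh)
    for key in ("critical_weight", "max_count", "components"):
        if key not in payload:
            raise ValueError(f"final-structure JSON missing field {key!r}")
    comps = [
        ComponentRecord(
            nodes=frozenset(c["nodes"]),
            edges=[(u, v, float(m)) for u, v, m in c["edges"]],
            order=int(c["order"]),
            size=int(c["size"]),
            diameter=int(c["diameter"]),
            vanishing_point=float(c["vanishing_point"]),
        )
        for c in payload["components"]
    ]
    return FinalStructure(
        components=comps,
        critical_weight=float(payload["critical_weight"]),
        max_count=int(payload["max_count"]),
    )


# ---------------------------------------------------------------------------
# viewer script export (PyMOL)

_COMPONENT_COLORS = [
    (0.894, 0.102, 0.110), (0.216, 0.494, 0.722), (0.302, 0.686, 0.290),
    (0.596, 0.306, 0.639), (1.000, 0.498, 0.000), (1.000, 1.000, 0.200),
    (0.651, 0.337, 0.157), (0.969, 0.506, 0.749), (0.600, 0.600, 0.600),
]


def _residue_centroids(structure_path: str | Path) -> dict[str, np.ndarray]:
    traj = md.load(str(structure_path))
    xyz = traj.xyz[0] * 10.0
    centroids: dict[str, np.ndarray] = {}
    for res in traj.topology.residues:
        idx = [a.index for a in res.atoms if a.element is None or a.element.symbol != "H"]
        if not idx:
            idx = [a.index for a in res.atoms]
        label = f"{res.chain.chain_id or 'A'}:{res.resSeq}:{res.name}"
        centroids[label] = xyz[idx].mean(axis=0)
    return centroids


def _cgo_cylinder(p1, p2, radius, color) -> str:
    vals = (
        list(map(float, p1)) + list(map(float, p2)) + [float(radius)]
        + list(color) + list(color)
    )
    return "CYLINDER, " + ", ".join("%.3f" % v for v in vals) + ","


def export_viewer_script(
    obj: DPCNGraph | list[ComponentRecord],
    structure_path: str | Path,
    out_path: str | Path,
    max_radius: float = 0.5,
) -> None:
    """Write a PyMOL script drawing the network on a 3D structure.

    Graph mode draws one cylinder per edge between residue centroids, blue
    for negative weights (more contacts in the initial state) and red for
    positive ones, radius proportional to magnitude. Component mode colors
    each component distinctly. Every node must resolve to a residue in the
    structure file.
    """
    centroids = _residue_centroids(structure_path)

    def centroid(label: str) -> np.ndarray:
        if label not in centroids:
            raise ValueError(
                f"residue label {label!r} not found in {structure_path}"
            )
        return centroids[label]

    lines = [
        "# PyMOL rendering script written by dpcnet %s" % __version__,
        "from pymol.cgo import CYLINDER",
        "from pymol import cmd",
        "obj = [",
    ]
    if isinstance(obj, DPCNGraph):
        mags = obj.magnitudes()
        scale = max_radius / mags.max() if len(mags) and mags.max() > 0 else 1.0
        for u, v, d in sorted(
            obj.graph.edges(data=True), key=lambda e: tuple(sorted(e[:2]))
        ):
            color = (0.8, 0.1, 0.1) if d["weight"] > 0 else (0.1, 0.1, 0.8)
            lines.append(
                _cgo_cylinder(
                    centroid(u), centroid(v), d["magnitude"] * scale, color
                )
            )
    else:
        all_mags = [m for c in obj for _, _, m in c.edges]
        top = max(all_mags) if all_mags else 1.0
        scale = max_radius / top if top > 0 else 1.0
        for ci, comp in enumerate(obj):
            color = _COMPONENT_COLORS[ci % len(_COMPONENT_COLORS)]
            for u, v, m in comp.edges:
                lines.append(_cgo_cylinder(centroid(u), centroid(v), m * scale, color))
    lines += ["]", 'cmd.load_cgo(obj, "dpcn_edges")']
    Path(out_path).write_text("\n".join(lines) + "\n")
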