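"""Average residue contact matrices from trajectory frame ensembles.

The pipeline implemented here is the contact-map half of a dynamical
perturbation contact network (DPCN) analysis:

1. at every frame, find all selected atom pairs within a distance cutoff
   (default 5 Angstrom) using a KD-tree neighbor query and record them in a
   binary atomic contact matrix ``A`` (``a_ij = 1`` iff atoms *i* and *j*
   are in contact);
2. average the per-frame binary matrices over the ensemble, giving mean
   contact frequencies in ``[0, 1]`` per atom pair;
3. project the averaged atomic matrix onto residues with binary incidence
   (transformation) matrices ``T`` (``t_ij = 1`` iff atom *i* belongs to
   residue *j*): ``R = T^t A T``, and zero the diagonal so intra-residue
   contacts are excluded.

``R`` is the adjacency matrix of the residue contact network for one
simulated state; two such matrices (e.g. apo and effector-bound) are
subtracted downstream to form the perturbation network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

DEFAULT_CUTOFF = 5.0  # Angstrom; robust choice for protein structure networks

ATOM_TABLE_COLUMNS = ["name", "element", "residue_index", "resname", "resseq", "chain"]


@dataclass
class FrameEnsemble:
    """Coordinates and atom metadata for one state's set of trajectory frames.

    Parameters
    ----------
    coordinates : ndarray, shape (F, N, 3)
        Cartesian coordinates in Angstrom, frame-major.
    atom_table : pandas.DataFrame
        One row per atom with columns ``name``, ``element``,
        ``residue_index`` (0-based contiguous ordinal), ``resname``,
        ``resseq`` (author residue number) and ``chain``.
    frame_provenance : list of (source, frame_index)
        Where each frame came from; purely informational.
    """

    coordinates: np.ndarray
    atom_table: pd.DataFrame
    frame_provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError(
                f"coordinates must have shape (F, N, 3), got {self.coordinates.shape}"
            )
        if self.n_frames < 1 or self.n_atoms < 2:
            raise ValueError("need at least 1 frame and 2 atoms")
        missing = [c for c in ATOM_TABLE_COLUMNS if c not in self.atom_table.columns]
        if missing:
            raise ValueError(f"atom_table missing columns: {missing}")
        if len(self.atom_table) != self.n_atoms:
            raise ValueError(
                f"atom_table has {len(self.atom_table)} rows for {self.n_atoms} atoms"
            )
        res = self.atom_table["residue_index"].to_numpy()
        if res.min() != 0 or not np.array_equal(
            np.unique(res), np.arange(res.max() + 1)
        ):
            raise ValueError("residue_index must be 0-based and contiguous")
        if not self.frame_provenance:
            self.frame_provenance = [("<memory>", i) for i in range(self.n_frames)]

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def n_residues(self) -> int:
        return int(self.atom_table["residue_index"].max()) + 1

    def residue_labels(self) -> list[str]:
        """``chain:resseq:resname`` label per residue ordinal."""
        first = self.atom_table.groupby("residue_index", sort=True).first()
        return [
            f"{r.chain}:{r.resseq}:{r.resname}" for r in first.itertuples()
        ]


@dataclass
class AtomSelection:
    """Boolean mask over the atoms of an ensemble."""

    mask: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("selection is empty: at least one atom must be selected")

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)


def _is_hydrogen(name: str, element: str) -> bool:
    # Element field wins when present; else strip leading digits from the
    # atom name (PDB convention, e.g. "1HB") and test the first letter.
    el = (element or "").strip()
    if el:
        return el.upper() == "H"
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1].upper() == "H"


def heavy_atom_selection(ensemble: FrameEnsemble) -> AtomSelection:
    """Default selection: the protein stripped of hydrogen atoms."""
    mask = np.array(
        [
            not _is_hydrogen(n, e)
            for n, e in zip(ensemble.atom_table["name"], ensemble.atom_table["element"])
        ]
    )
    return AtomSelection(mask, "heavy atoms (hydrogens excluded)")


def backbone_selection(ensemble: FrameEnsemble) -> AtomSelection:
    """Protein backbone heavy atoms (N, CA, C, O)."""
    names = ensemble.atom_table["name"].str.strip().str.upper()
    mask = names.isin(["N", "CA", "C", "O"]).to_numpy()
    return AtomSelection(mask, "backbone atoms (N, CA, C, O)")


def sidechain_selection(ensemble: FrameEnsemble) -> AtomSelection:
    """Heavy atoms that are not part of the backbone."""
    heavy = heavy_atom_selection(ensemble).mask
    names = ensemble.atom_table["name"].str.strip().str.upper()
    mask = heavy & ~names.isin(["N", "CA", "C", "O"]).to_numpy()
    return AtomSelection(mask, "sidechain heavy atoms")


@dataclass
class AtomicContactMatrix:
    """Binary symmetric per-frame atomic contact matrix with zero diagonal."""

    entries: np.ndarray
    cutoff: float

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries)


def find_atomic_contacts(
    frame: np.ndarray, selection: AtomSelection, cutoff: float = DEFAULT_CUTOFF
) -> AtomicContactMatrix:
    """Binary atomic contact matrix for a single frame.

    Two selected atoms are in contact when their Euclidean distance is
    ``<= cutoff`` (closed predicate). Uses a KD-tree pair query; entries for
    unselected atoms are zero. Intra-residue pairs are recorded here — they
    are discarded later by zeroing the residue-matrix diagonal.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.shape[1] != 3:
        raise ValueError(f"frame must have shape (N, 3), got {frame.shape}")
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if not np.isfinite(frame).all():
        raise ValueError("frame contains non-finite coordinates")
    n = frame.shape[0]
    entries = np.zeros((n, n), dtype=np.uint8)
    idx = selection.indices
    pairs = cKDTree(frame[idx]).query_pairs(r=cutoff, output_type="ndarray")
    if len(pairs):
        gi, gj = idx[pairs[:, 0]], idx[pairs[:, 1]]
        entries[gi, gj] = 1
        entries[gj, gi] = 1
    return AtomicContactMatrix(entries, cutoff)


def _contact_count_matrix(
    ensemble: FrameEnsemble, selection: AtomSelection, cutoff: float
) -> np.ndarray:
    """Integer per-pair contact counts over all frames (exact)."""
    n = ensemble.n_atoms
    counts = np.zeros((n, n), dtype=np.int64)
    idx = selection.indices
    for f in range(ensemble.n_frames):
        frame = ensemble.coordinates[f]
        if not np.isfinite(frame).all():
            raise ValueError(f"frame {f} contains non-finite coordinates")
        pairs = cKDTree(frame[idx]).query_pairs(r=cutoff, output_type="ndarray")
        if len(pairs):
            gi, gj = idx[pairs[:, 0]], idx[pairs[:, 1]]
            counts[gi, gj] += 1
            counts[gj, gi] += 1
    return counts


def average_contact_matrix(
    ensemble: FrameEnsemble,
    selection: AtomSelection | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> np.ndarray:
    """Frame-averaged atomic contact matrix, entries in ``[0, 1]``.

    Each entry is the exact rational fraction (frames in contact) / F,
    evaluated as a single integer-count division so no accumulation error
    is possible.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if selection is None:
        selection = heavy_atom_selection(ensemble)
    _warn_if_collapsed(ensemble)
    counts = _contact_count_matrix(ensemble, selection, cutoff)
    return counts / float(ensemble.n_frames)


def _warn_if_collapsed(ensemble: FrameEnsemble) -> None:
    # A bounding box far too small for the atom count usually means the
    # frames were wrapped into a periodic cell fragment; this module does
    # not re-image coordinates.
    import warnings

    span = ensemble.coordinates.max(axis=(0, 1)) - ensemble.coordinates.min(axis=(0, 1))
    if float(span.max()) < 2.0 * ensemble.n_atoms ** (1 / 3):
        warnings.warn(
            "frame bounding box is implausibly small for the atom count; "
            "coordinates may be PBC-wrapped (this module does not re-image)",
            stacklevel=3,
        )


@dataclass
class TransformationMatrix:
    """Atom-to-residue binary incidence matrix ``T`` (``t_ij = 1`` iff atom
    *i* belongs to residue *j* and is selected)."""

    entries: np.ndarray

    @property
    def atom_counts(self) -> np.ndarray:
        """Selected atoms per residue (column sums of ``T``)."""
        return self.entries.sum(axis=0)


def build_transformation(
    atom_table: pd.DataFrame, selection: AtomSelection
) -> TransformationMatrix:
    """Build ``T`` from the atom table; deselected atoms get all-zero rows."""
    res = atom_table["residue_index"]
    if res.isna().any():
        bad = atom_table.index[res.isna()].tolist()
        raise ValueError(f"atoms with no residue assignment: {bad}")
    res = res.to_numpy(dtype=int)
    n_atoms = len(atom_table)
    n_res = int(res.max()) + 1
    if len(selection.mask) != n_atoms:
        raise ValueError("selection mask length does not match atom table")
    t = np.zeros((n_atoms, n_res), dtype=np.int8)
    sel = selection.indices
    t[sel, res[sel]] = 1
    return TransformationMatrix(t)


@dataclass
class AverageResidueContactMatrix:
    """Symmetric nonnegative residue matrix of mean atomic contacts per
    frame, diagonal identically zero."""

    entries: np.ndarray
    residue_labels: list[str]
    n_frames: int
    cutoff: float = DEFAULT_CUTOFF
    selection_description: str = ""

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        m = self.entries.shape[0]
        if self.entries.shape != (m, m):
            raise ValueError("entries must be square")
        if len(self.residue_labels) != m:
            raise ValueError(
                f"{len(self.residue_labels)} labels for a {m}x{m} matrix"
            )

    @property
    def n_residues(self) -> int:
        return self.entries.shape[0]


def project_to_residues(
    avg_atomic: np.ndarray,
    t_row: TransformationMatrix,
    t_col: TransformationMatrix | None = None,
) -> np.ndarray:
    """Project an atomic matrix onto residues: ``R = T_row^t A T_col``,
    diagonal zeroed.

    Distinct row/column transformations describe asymmetric contacts
    (different atom selections on the two sides); with equal
    transformations the result is symmetric.
    """
    if t_col is None:
        t_col = t_row
    avg_atomic = np.asarray(avg_atomic, dtype=float)
    if avg_atomic.shape[0] != t_row.entries.shape[0] or avg_atomic.shape[1] != t_col.entries.shape[0]:
        raise ValueError(
            f"dimension mismatch: A is {avg_atomic.shape}, T_row has "
            f"{t_row.entries.shape[0]} atoms, T_col has {t_col.entries.shape[0]}"
        )
    r = t_row.entries.astype(float).T @ avg_atomic @ t_col.entries.astype(float)
    if t_row.entries.shape == t_col.entries.shape and np.array_equal(
        t_row.entries, t_col.entries
    ):
        r = (r + r.T) / 2.0  # restore exact symmetry lost to summation order
    np.fill_diagonal(r, 0.0)
    return r


def residue_contact_matrix(
    ensemble: FrameEnsemble,
    selection: AtomSelection | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> AverageResidueContactMatrix:
    """Full pipeline for one state: frames -> averaged atomic contacts ->
    residue projection."""
    if selection is None:
        selection = heavy_atom_selection(ensemble)
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    _warn_if_collapsed(ensemble)
    # project the integer contact counts and divide by F last: the result
    # is then the exact rational (summed counts)/F, bitwise symmetric
    counts = _contact_count_matrix(ensemble, selection, cutoff)
    t = build_transformation(ensemble.atom_table, selection)
    r = project_to_residues(counts.astype(float), t) / float(ensemble.n_frames)
    return AverageResidueContactMatrix(
        r,
        ensemble.residue_labels(),
        ensemble.n_frames,
        cutoff=cutoff,
        selection_description=selection.description,
    )
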