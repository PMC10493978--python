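import numpy as np
import pandas as pd
import pytest

from dpcnet.contacts import ATOM_TABLE_COLUMNS, AtomSelection, FrameEnsemble
from dpcnet.synthetic import PerturbationSpec, PlantedGraphSpec


def random_frame(n_atoms: int, box: float, rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(0.0, box, size=(n_atoms, 3))


def simple_atom_table(residue_sizes: list[int]) -> pd.DataFrame:
    """Atom table with the given number of (heavy) atoms per residue."""
    rows = []
    for res, size in enumerate(residue_sizes):
        for j in range(size):
            name = "CA" if j == 0 else f"C{j}"
            rows.append((name, "C", res, "ALA", res + 1, "A"))
    return pd.DataFrame(rows, columns=ATOM_TABLE_COLUMNS)


@pytest.fixture
def small_ensemble() -> FrameEnsemble:
    """10 frames x 30 atoms, 6 residues of 5 atoms, in a 12 A box."""
    rng = np.random.default_rng(42)
    coords = rng.uniform(0.0, 12.0, size=(10, 30, 3))
    return FrameEnsemble(coords, simple_atom_table([5] * 6))


@pytest.fixture
def all_selection(small_ensemble) -> AtomSelection:
    return AtomSelection(np.ones(small_ensemble.n_atoms, dtype=bool), "all")


@pytest.fixture
def perturbation_spec() -> PerturbationSpec:
    """Six planted pairs with mixed signs; weights exact by construction."""
    return PerturbationSpec(
        n_residues=14,
        pairs=[(0, 2), (1, 5), (3, 8), (4, 9), (6, 11), (7, 13)],
        deltas=[0.5, -0.25, 0.75, -0.2, 0.25, 0.6],
        n_atom_pairs=[1, 2, 1, 3, 1, 2],
        n_frames=20,
        base_frequency=0.25,
        seed=7,
    )


@pytest.fixture
def planted_spec() -> PlantedGraphSpec:
    """Five clusters: one long path pathway, star, cycle, dyad, random."""
    return PlantedGraphSpec(
        clusters=[(8, "path"), (4, "star"), (5, "cycle"), (2, "path"), (6, "random")],
        internal_range=(5.0, 8.0),
        bridge_range=(0.5, 2.0),
        seed=11,
    )
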