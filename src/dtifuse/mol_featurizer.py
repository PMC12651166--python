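"""SMILES to padded molecular-graph featurization.

A molecule is converted to a graph G = (V, E) whose nodes carry a 74-dim
feature vector per atom, the canonical atom descriptor set used throughout
graph-based DTI work: atom-type one-hot (42 common elements + "other", 43
bits), degree one-hot (0-10), implicit valence one-hot (0-6), formal charge,
radical-electron count, hybridization one-hot (SP, SP2, SP3, SP3D, SP3D2),
aromaticity flag, and total-hydrogen one-hot (0-4).  The graph is zero-padded
to a fixed atom count ``n_atoms_max`` so molecules batch; the adjacency
carries covalent bonds plus self-loops on real atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.error")

logger = logging.getLogger("dtifuse")


class FeaturizationError(ValueError):
    """Raised when a SMILES string cannot be featurized."""


ATOM_SYMBOLS = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg",
]  # 42 symbols; index 42 is the "other" bucket

HYBRIDIZATIONS = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]

ATOM_FEAT_DIM = 74

# one-hot block boundaries within the 74-dim vector (start, stop)
FEATURE_BLOCKS = {
    "atom_type": (0, 43),
    "degree": (43, 54),
    "implicit_valence": (54, 61),
    "formal_charge": (61, 62),
    "radical_electrons": (62, 63),
    "hybridization": (63, 68),
    "aromatic": (68, 69),
    "total_h": (69, 74),
}


@dataclass
class MolecularGraph:
    """Padded molecular graph: features, adjacency with self-loops, mask."""

    n_atoms: int
    node_features: np.ndarray    # (N_d, 74); rows >= n_atoms are zero
    adjacency: np.ndarray        # (N_d, N_d); bonds + self-loops on real atoms
    node_mask: np.ndarray        # (N_d,) in {0, 1}

    def __post_init__(self):
        assert self.node_features.shape == (self.adjacency.shape[0],
                                            ATOM_FEAT_DIM)


@dataclass
class DenseDrugInput:
    """Eq.-1 style dense drug input X_d = M_d W_d^T."""

    features: np.ndarray            # (N_d, D)
    projection_weights: np.ndarray  # (D, 74)


def _one_hot(value, choices, other: bool = False) -> list:
    vec = [0.0] * (len(choices) + (1 if other else 0))
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        if other:
            vec[-1] = 1.0
        else:
            raise
    return vec


def atom_features(atom: Chem.Atom) -> np.ndarray:
    """The 74-dim descriptor of a single RDKit atom."""
    feats = []
    feats += _one_hot(atom.GetSymbol(), ATOM_SYMBOLS, other=True)
    feats += _one_hot(min(atom.GetDegree(), 10), list(range(11)))
    feats += _one_hot(min(atom.GetImplicitValence(), 6), list(range(7)))
    feats.append(float(atom.GetFormalCharge()))
    feats.append(float(atom.GetNumRadicalElectrons()))
    hyb = atom.GetHybridization()
    if hyb not in HYBRIDIZATIONS:
        hyb = Chem.HybridizationType.SP3   # rare non-organic fallback
    feats += _one_hot(hyb, HYBRIDIZATIONS)
    feats.append(1.0 if atom.GetIsAromatic() else 0.0)
    feats += _one_hot(min(atom.GetTotalNumHs(), 4), list(range(5)))
    out = np.asarray(feats, dtype=np.float32)
    assert out.shape == (ATOM_FEAT_DIM,)
    return out


def featurize_atoms(smiles: str, n_atoms_max: int = 290) -> MolecularGraph:
    """Featurize one SMILES string into a padded :class:`MolecularGraph`.

    Raises :class:`FeaturizationError` for unparsable SMILES, empty
    molecules, or molecules with more than ``n_atoms_max`` atoms (molecules
    are never silently truncated).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"could not parse SMILES {smiles!r}")
    n = mol.GetNumAtoms()
    if n == 0:
        raise FeaturizationError(f"SMILES {smiles!r} has no atoms")
    if n > n_atoms_max:
        raise FeaturizationError(
            f"molecule {smiles!r} has {n} atoms, exceeding the padded "
            f"maximum n_atoms_max={n_atoms_max}")

    feats = np.zeros((n_atoms_max, ATOM_FEAT_DIM), dtype=np.float32)
    for atom in mol.GetAtoms():
        feats[atom.GetIdx()] = atom_features(atom)

    adj = np.zeros((n_atoms_max, n_atoms_max), dtype=np.float32)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adj[i, j] = adj[j, i] = 1.0
    adj[np.arange(n), np.arange(n)] = 1.0   # self-loops on real atoms only

    mask = np.zeros(n_atoms_max, dtype=np.float32)
    mask[:n] = 1.0
    return MolecularGraph(n_atoms=n, node_features=feats, adjacency=adj,
                          node_mask=mask)


def normalize_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Symmetric degree normalization D^{-1/2} A D^{-1/2}.

    Zero-degree (padding) rows stay zero.
    """
    deg = adjacency.sum(axis=-1)
    inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-12)), 0.0)
    return (adjacency * inv_sqrt[..., :, None] * inv_sqrt[..., None, :]
            ).astype(adjacency.dtype)


def project_features(graph: MolecularGraph,
                     weights: np.ndarray) -> DenseDrugInput:
    """Dense drug input X_d = M_d W_d^T from the node-feature matrix."""
    weights = np.asarray(weights, dtype=np.float32)
    if weights.ndim != 2 or weights.shape[1] != ATOM_FEAT_DIM:
        raise ValueError(
            f"projection weights must be (D, {ATOM_FEAT_DIM}); "
            f"got {weights.shape}")
    feats = graph.node_features @ weights.T
    return DenseDrugInput(features=feats, projection_weights=weights)


class GraphCache:
    """Featurized-graph cache keyed by canonical SMILES."""

    def __init__(self, n_atoms_max: int):
        self.n_atoms_max = n_atoms_max
        self._store: dict = {}

    def get(self, smiles: str) -> MolecularGraph:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise FeaturizationError(f"could not parse SMILES {smiles!r}")
        key = Chem.MolToSmiles(mol)
        if key not in self._store:
            self._store[key] = featurize_atoms(smiles, self.n_atoms_max)
        return self._store[key]
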