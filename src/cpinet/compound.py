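"""SMILES -> molecular graph featurization.

A compound is a graph over its heavy atoms (hydrogens stay implicit, so
atom indices line up with heavy-atom contact labels).  Atom and bond
feature layouts are fixed-width one-hot blocks; the exact composition is a
package choice, kept configurable through the module constants below.

Atom features (f_atom = 28):
    element one-hot over ``ELEMENTS`` + "other"      11
    degree one-hot 0..5 (clipped)                     6
    formal charge one-hot -2..+2 (clipped)            5
    implicit-H count one-hot 0..4 (clipped)           5
    aromatic flag                                     1

Bond features (f_bond = 6): bond-order one-hot (single/double/triple/
aromatic) + conjugated flag + in-ring flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

__all__ = [
    "CompoundGraph",
    "smiles_to_graph",
    "atom_feature_vector",
    "bond_feature_vector",
    "F_ATOM",
    "F_BOND",
]

ELEMENTS = ("C", "N", "O", "S", "F", "P", "Cl", "Br", "I", "B")
MAX_DEGREE = 5
CHARGE_RANGE = (-2, 2)
MAX_IMPLICIT_H = 4
HETEROATOMS = frozenset({"N", "O", "S"})

F_ATOM = len(ELEMENTS) + 1 + (MAX_DEGREE + 1) + \
    (CHARGE_RANGE[1] - CHARGE_RANGE[0] + 1) + (MAX_IMPLICIT_H + 1) + 1
F_BOND = 6

_BOND_ORDER_SLOT = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}


@dataclass
class CompoundGraph:
    """Heavy-atom molecular graph with directed edge list.

    Edges are stored in both directions; rows of `bond_features` align with
    `edge_src`/`edge_dst` and are identical for the two directions of a
    bond.  `atom_order` is the parser's heavy-atom order, the indexing used
    by interaction-site labels.
    """

    n_atoms: int
    atom_features: np.ndarray          # (N_m, F_ATOM)
    edge_src: np.ndarray               # (n_directed_edges,)
    edge_dst: np.ndarray               # (n_directed_edges,)
    bond_features: np.ndarray          # (n_directed_edges, F_BOND)
    elements: tuple[str, ...]          # element symbol per atom

    @property
    def edges(self) -> list[tuple[int, int]]:
        return list(zip(self.edge_src.tolist(), self.edge_dst.tolist()))

    @property
    def atom_order(self) -> np.ndarray:
        return np.arange(self.n_atoms)

    @property
    def heteroatom_mask(self) -> np.ndarray:
        """True for N/O/S atoms (the usual polar-contact donors/acceptors)."""
        return np.array([el in HETEROATOMS for el in self.elements])


def _one_hot(index: int, size: int) -> np.ndarray:
    v = np.zeros(size)
    v[index] = 1.0
    return v


def atom_feature_vector(atom: Chem.Atom) -> np.ndarray:
    """Featurize one RDKit atom; unknown elements use the "other" slot."""
    sym = atom.GetSymbol()
    elem_idx = ELEMENTS.index(sym) if sym in ELEMENTS else len(ELEMENTS)
    degree = min(atom.GetDegree(), MAX_DEGREE)
    charge = int(np.clip(atom.GetFormalCharge(), *CHARGE_RANGE))
    n_h = min(atom.GetTotalNumHs(), MAX_IMPLICIT_H)
    return np.concatenate([
        _one_hot(elem_idx, len(ELEMENTS) + 1),
        _one_hot(degree, MAX_DEGREE + 1),
        _one_hot(charge - CHARGE_RANGE[0],
                 CHARGE_RANGE[1] - CHARGE_RANGE[0] + 1),
        _one_hot(n_h, MAX_IMPLICIT_H + 1),
        np.array([1.0 if atom.GetIsAromatic() else 0.0]),
    ])


def bond_feature_vector(bond: Chem.Bond) -> np.ndarray:
    """One-hot bond order + conjugation and ring flags."""
    v = np.zeros(F_BOND)
    slot = _BOND_ORDER_SLOT.get(bond.GetBondType())
    if slot is None:
        slot = 3 if bond.GetIsAromatic() else 0
    v[slot] = 1.0
    if bond.GetIsConjugated():
        v[4] = 1.0
    if bond.IsInRing():
        v[5] = 1.0
    return v


def smiles_to_graph(smiles: str) -> CompoundGraph:
    """Parse a SMILES string into a :class:`CompoundGraph`.

    Hydrogens remain implicit; disconnected components (salts) are kept in
    one graph with no edges between them, preserving atom indexing.
    Raises ``ValueError`` for unparseable SMILES or molecules with no heavy
    atoms.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: '{smiles}'")
    n = mol.GetNumAtoms()
    if n == 0:
        raise ValueError(f"SMILES '{smiles}' has no heavy atoms")
    atom_feats = np.stack([atom_feature_vector(a) for a in mol.GetAtoms()])
    src, dst, bond_feats = [], [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bf = bond_feature_vector(bond)
        src.extend((i, j))
        dst.extend((j, i))
        bond_feats.extend((bf, bf))
    return CompoundGraph(
        n_atoms=n,
        atom_features=atom_feats,
        edge_src=np.array(src, dtype=np.intp),
        edge_dst=np.array(dst, dtype=np.intp),
        bond_features=(np.stack(bond_feats) if bond_feats
                       else np.zeros((0, F_BOND))),
        elements=tuple(a.GetSymbol() for a in mol.GetAtoms()),
    )
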