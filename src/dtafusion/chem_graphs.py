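"""Molecular graph construction: atom-bond graphs and pharmacophore graphs.

A compound is modelled from two complementary views that share one atom
index space:

* the **atom-bond graph** — atoms as nodes, covalent bonds as attributed
  (directed, symmetric) edges carrying bond type and stereo information;
* the **pharmacophore graph** — a coarse functional-unit graph in which
  every ring (smallest set of smallest rings) is one node and every
  remaining acyclic bond, together with its two atoms, is one node.
  Units are adjacent exactly when they share at least one atom.

The decomposition partitions the bond set (each bond belongs to exactly
one unit) and covers the atom set (every atom sits in at least one
unit). Hydrogens are implicit and never become nodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem

__all__ = [
    "AtomRecord",
    "BondRecord",
    "Molecule",
    "AtomBondGraph",
    "PharmUnit",
    "PharmacophoreGraph",
    "MolGraphPair",
    "SmilesParseError",
    "parse_smiles",
    "atom_descriptor",
    "fallback_atom_features",
    "build_atom_bond_graph",
    "decompose_pharm_units",
    "featurize_pharm_node",
    "build_pharmacophore_graph",
    "build_mol_graph_pair",
    "ATOM_VOCABULARY",
    "BOND_TYPES",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


# Versioned element vocabulary for the fallback one-hot descriptor.
# The final slot is a catch-all for anything outside the list.
ATOM_VOCABULARY: tuple[str, ...] = (
    "C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B", "Si", "Se", "Na", "K", "*",
)
BOND_TYPES: tuple[str, ...] = ("SINGLE", "DOUBLE", "TRIPLE", "AROMATIC")
_CHIRAL_TAGS: tuple[str, ...] = ("CHI_UNSPECIFIED", "CHI_TETRAHEDRAL_CW", "CHI_TETRAHEDRAL_CCW", "CHI_OTHER")
_BOND_STEREO: tuple[str, ...] = ("STEREONONE", "STEREOZ", "STEREOE", "STEREOCIS", "STEREOTRANS", "STEREOANY")


@dataclass(frozen=True)
class AtomRecord:
    element: str
    degree: int
    aromatic: bool
    formal_charge: int
    chiral_tag: str
    in_ring: bool


@dataclass(frozen=True)
class BondRecord:
    atom_i: int
    atom_j: int
    bond_type: str
    stereo: str
    in_ring: bool


@dataclass
class Molecule:
    """Parsed molecule with 0-based contiguous atom indexing."""

    atoms: list[AtomRecord]
    bonds: list[BondRecord]
    smiles_canonical: str
    _rdkit: Chem.Mol = field(repr=False, compare=False, default=None)

    @property
    def num_atoms(self) -> int:
        return len(self.atoms)

    @property
    def num_bonds(self) -> int:
        return len(self.bonds)

    def rdkit_mol(self) -> Chem.Mol:
        if self._rdkit is None:
            self._rdkit = Chem.MolFromSmiles(self.smiles_canonical)
        return self._rdkit


@dataclass
class AtomBondGraph:
    """Atoms as nodes; each chemical bond as a symmetric directed edge pair."""

    node_features: np.ndarray  # N x F_a
    edge_index: np.ndarray  # E x 2, directed
    edge_features: np.ndarray  # E x F_e

    @property
    def num_nodes(self) -> int:
        return self.node_features.shape[0]

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency (no self-loops); cached."""
        cached = getattr(self, "_adj", None)
        if cached is None:
            n = self.num_nodes
            cached = np.zeros((n, n))
            if len(self.edge_index):
                cached[self.edge_index[:, 0], self.edge_index[:, 1]] = 1.0
            self._adj = cached
        return cached

    def edge_feature_matrix(self) -> np.ndarray:
        """Dense N x N x F_e edge-attribute array (zeros off-edge); cached."""
        cached = getattr(self, "_edge_mat", None)
        if cached is None:
            n = self.num_nodes
            fe = self.edge_features.shape[1] if self.edge_features.ndim == 2 else 1
            cached = np.zeros((n, n, fe))
            if len(self.edge_index):
                cached[self.edge_index[:, 0], self.edge_index[:, 1]] = self.edge_features
            self._edge_mat = cached
        return cached

    def to_json(self) -> str:
        return json.dumps(
            {
                "node_features": self.node_features.tolist(),
                "edge_index": self.edge_index.tolist(),
                "edge_features": self.edge_features.tolist(),
            }
        )


@dataclass(frozen=True)
class PharmUnit:
    """One coarse functional unit: a ring, or an acyclic bond with its atoms."""

    kind: str  # "ring" | "acyclic_bond"
    atom_ids: frozenset[int]
    bond_ids: frozenset[int]


@dataclass
class PharmacophoreGraph:
    units: list[PharmUnit]
    node_features: np.ndarray  # U x F_p
    edge_index: np.ndarray  # symmetric, no self-loops

    @property
    def num_nodes(self) -> int:
        return len(self.units)

    def adjacency(self) -> np.ndarray:
        cached = getattr(self, "_adj", None)
        if cached is None:
            n = self.num_nodes
            cached = np.zeros((n, n))
            if len(self.edge_index):
                cached[self.edge_index[:, 0], self.edge_index[:, 1]] = 1.0
            self._adj = cached
        return cached

    def to_json(self) -> str:
        return json.dumps(
            {
                "units": [
                    {"kind": u.kind, "atom_ids": sorted(u.atom_ids), "bond_ids": sorted(u.bond_ids)}
                    for u in self.units
                ],
                "node_features": self.node_features.tolist(),
                "edge_index": self.edge_index.tolist(),
            }
        )


@dataclass
class MolGraphPair:
    """Both molecular views of one compound, sharing the atom index space."""

    molecule: Molecule
    atom_bond: AtomBondGraph
    pharmacophore: PharmacophoreGraph


def parse_smiles(smiles: str) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule` (implicit hydrogens).

    Raises :class:`SmilesParseError` for empty or unparsable input, naming
    the offending string.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    atoms = [
        AtomRecord(
            element=a.GetSymbol(),
            degree=a.GetDegree(),
            aromatic=a.GetIsAromatic(),
            formal_charge=a.GetFormalCharge(),
            chiral_tag=str(a.GetChiralTag()),
            in_ring=a.IsInRing(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = [
        BondRecord(
            atom_i=b.GetBeginAtomIdx(),
            atom_j=b.GetEndAtomIdx(),
            bond_type=str(b.GetBondType()),
            stereo=str(b.GetStereo()),
            in_ring=b.IsInRing(),
        )
        for b in mol.GetBonds()
    ]
    return Molecule(atoms=atoms, bonds=bonds, smiles_canonical=Chem.MolToSmiles(mol), _rdkit=mol)


def _one_hot(value: str, vocab: Sequence[str]) -> np.ndarray:
    vec = np.zeros(len(vocab))
    try:
        vec[vocab.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


def atom_descriptor(atom: AtomRecord) -> np.ndarray:
    """Handcrafted per-atom descriptor (versioned vocabulary, fixed width)."""
    return np.concatenate(
        [
            _one_hot(atom.element, ATOM_VOCABULARY),
            [atom.degree, float(atom.aromatic), atom.formal_charge],
            _one_hot(atom.chiral_tag, _CHIRAL_TAGS),
            [float(atom.in_ring)],
        ]
    )


ATOM_DESCRIPTOR_DIM = len(ATOM_VOCABULARY) + 3 + len(_CHIRAL_TAGS) + 1


def fallback_atom_features(mol: Molecule) -> np.ndarray:
    """N x F descriptor matrix used when no pre-trained provider is attached."""
    if mol.num_atoms == 0:
        return np.zeros((0, ATOM_DESCRIPTOR_DIM))
    return np.stack([atom_descriptor(a) for a in mol.atoms])


def _bond_edge_features(bond: BondRecord) -> np.ndarray:
    return np.concatenate([_one_hot(bond.bond_type, BOND_TYPES), _one_hot(bond.stereo, _BOND_STEREO)])


BOND_FEATURE_DIM = len(BOND_TYPES) + len(_BOND_STEREO)


def build_atom_bond_graph(
    mol: Molecule,
    embedder: Callable[[Molecule], np.ndarray] | None = None,
) -> AtomBondGraph:
    """Build the atom-level view.

    `embedder` maps a molecule to an N x dim node-feature matrix (e.g. a
    pre-trained atom embedding provider); without one the handcrafted
    descriptor matrix is used. Each chemical bond contributes two directed
    edges carrying identical bond-type + stereo attributes.
    """
    node_features = fallback_atom_features(mol) if embedder is None else np.asarray(embedder(mol), dtype=float)
    if node_features.shape[0] != mol.num_atoms:
        raise ValueError(
            f"embedder returned {node_features.shape[0]} rows for a molecule with {mol.num_atoms} atoms"
        )
    edges: list[tuple[int, int]] = []
    feats: list[np.ndarray] = []
    for bond in mol.bonds:
        f = _bond_edge_features(bond)
        edges.append((bond.atom_i, bond.atom_j))
        feats.append(f)
        edges.append((bond.atom_j, bond.atom_i))
        feats.append(f)
    edge_index = np.asarray(edges, dtype=int).reshape(-1, 2)
    edge_features = np.asarray(feats).reshape(-1, BOND_FEATURE_DIM) if feats else np.zeros((0, BOND_FEATURE_DIM))
    return AtomBondGraph(node_features=node_features, edge_index=edge_index, edge_features=edge_features)


def decompose_pharm_units(mol: Molecule) -> list[PharmUnit]:
    """Partition a molecule into ring units (SSSR) and acyclic-bond units.

    Ring units come first, ordered by their lowest atom index; acyclic
    units follow in bond-index order. A bond that belongs to a ring is
    assigned to exactly one ring unit (ties broken by ring order), so the
    unit bond sets partition the molecule's bonds. Isolated atoms (no
    bonds) yield one degenerate unit holding just that atom.
    """
    rd = mol.rdkit_mol()
    ring_info = rd.GetRingInfo()
    rings = sorted(
        zip(ring_info.AtomRings(), ring_info.BondRings()),
        key=lambda pair: min(pair[0]),
    )

    assigned_bonds: set[int] = set()
    units: list[PharmUnit] = []
    for ring_atoms, ring_bonds in rings:
        new_bonds = frozenset(ring_bonds) - assigned_bonds
        if not new_bonds:
            # symmetry-duplicated ring: all its bonds already claimed
            continue
        assigned_bonds |= new_bonds
        units.append(PharmUnit(kind="ring", atom_ids=frozenset(ring_atoms), bond_ids=new_bonds))

    covered_atoms = set().union(*(u.atom_ids for u in units)) if units else set()
    for idx, bond in enumerate(mol.bonds):
        if idx in assigned_bonds:
            continue
        units.append(
            PharmUnit(
                kind="acyclic_bond",
                atom_ids=frozenset((bond.atom_i, bond.atom_j)),
                bond_ids=frozenset((idx,)),
            )
        )
        covered_atoms |= {bond.atom_i, bond.atom_j}

    # isolated atoms (e.g. a bare ion) get a degenerate unit so the
    # atom-cover invariant holds
    for atom_idx in range(mol.num_atoms):
        if atom_idx not in covered_atoms:
            units.append(PharmUnit(kind="acyclic_bond", atom_ids=frozenset((atom_idx,)), bond_ids=frozenset()))
    return units


def featurize_pharm_node(unit: PharmUnit, mol: Molecule) -> np.ndarray:
    """Fixed-width, atom-order-invariant descriptor for one pharmacophore unit.

    Concatenates sums and means of the member atoms' descriptors with
    bond-type counts and basic unit statistics (size, ring flag).
    """
    atom_vecs = [atom_descriptor(mol.atoms[i]) for i in sorted(unit.atom_ids)]
    atom_mat = np.stack(atom_vecs) if atom_vecs else np.zeros((1, ATOM_DESCRIPTOR_DIM))
    bond_type_counts = np.zeros(len(BOND_TYPES))
    for b_idx in unit.bond_ids:
        bond_type_counts += _one_hot(mol.bonds[b_idx].bond_type, BOND_TYPES)
    return np.concatenate(
        [
            atom_mat.sum(axis=0),
            atom_mat.mean(axis=0),
            bond_type_counts,
            [len(unit.atom_ids), len(unit.bond_ids), float(unit.kind == "ring")],
        ]
    )


PHARM_FEATURE_DIM = 2 * ATOM_DESCRIPTOR_DIM + len(BOND_TYPES) + 3


def build_pharmacophore_graph(mol: Molecule) -> PharmacophoreGraph:
    """Units as nodes; two units are adjacent iff they share an atom."""
    units = decompose_pharm_units(mol)
    node_features = (
        np.stack([featurize_pharm_node(u, mol) for u in units]) if units else np.zeros((0, PHARM_FEATURE_DIM))
    )
    edges: list[tuple[int, int]] = []
    for i in range(len(units)):
        for j in range(i + 1, len(units)):
            if units[i].atom_ids & units[j].atom_ids:
                edges.append((i, j))
                edges.append((j, i))
    edge_index = np.asarray(edges, dtype=int).reshape(-1, 2)
    return PharmacophoreGraph(units=units, node_features=node_features, edge_index=edge_index)


def build_mol_graph_pair(
    smiles: str,
    embedder: Callable[[Molecule], np.ndarray] | None = None,
) -> MolGraphPair:
    """Parse SMILES and build both molecular views."""
    mol = parse_smiles(smiles)
    return MolGraphPair(
        molecule=mol,
        atom_bond=build_atom_bond_graph(mol, embedder),
        pharmacophore=build_pharmacophore_graph(mol),
    )
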