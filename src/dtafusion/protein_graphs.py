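"""Protein representations: weighted residue contact graphs + pooled sequence embeddings.

A protein is modelled from two dimensions. The *conformation* view is a
residue contact graph: residues are nodes and an undirected edge links
residues i and j whenever their (max-symmetrized) predicted contact
probability strictly exceeds 0.5; the probability itself becomes the
edge weight, so stronger contacts propagate more signal. The *sequence*
view is a single vector obtained by averaging per-residue embeddings
over the length dimension.

Residue node features fall back to a handcrafted descriptor:
one-hot(21) over the standard amino-acid alphabet plus X, concatenated
with Kyte-Doolittle hydropathy, net side-chain charge at neutral pH, a
polarity flag, and residue molecular weight (scaled by 1/100).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "ResidueContactGraph",
    "SequenceEmbedding",
    "ProteinRep",
    "residue_descriptor",
    "sequence_feature_matrix",
    "build_contact_graph",
    "pool_sequence_embedding",
    "read_fasta",
    "CONTACT_THRESHOLD",
    "RESIDUE_DESCRIPTOR_DIM",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET = AMINO_ACIDS + "X"
CONTACT_THRESHOLD = 0.5

# Kyte-Doolittle hydropathy index
_HYDROPATHY = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4, "H": -3.2,
    "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5,
    "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}
_CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.1}
_POLAR = set("STNQCYHKRDE")
# average residue masses (Da)
_MW = {
    "A": 71.08, "C": 103.14, "D": 115.09, "E": 129.12, "F": 147.18, "G": 57.05,
    "H": 137.14, "I": 113.16, "K": 128.17, "L": 113.16, "M": 131.19, "N": 114.10,
    "P": 97.12, "Q": 128.13, "R": 156.19, "S": 87.08, "T": 101.10, "V": 99.13,
    "W": 186.21, "Y": 163.18,
}
_MW_MEAN = float(np.mean(list(_MW.values())))

RESIDUE_DESCRIPTOR_DIM = len(_ALPHABET) + 4


def residue_descriptor(aa: str) -> np.ndarray:
    """Fixed-width descriptor for one residue code.

    'X' (or any unknown code mapped to X upstream) gets an all-zero
    one-hot block with neutral physicochemical defaults (hydropathy 0,
    charge 0, apolar, mean residue mass).
    """
    if len(aa) != 1:
        raise ValueError(f"expected a one-letter code, got {aa!r}")
    aa = aa.upper()
    if aa not in _ALPHABET:
        raise ValueError(f"unknown residue code {aa!r}")
    one_hot = np.zeros(len(_ALPHABET))
    if aa != "X":
        one_hot[_ALPHABET.index(aa)] = 1.0
    return np.concatenate(
        [
            one_hot,
            [
                _HYDROPATHY.get(aa, 0.0),
                _CHARGE.get(aa, 0.0),
                float(aa in _POLAR),
                _MW.get(aa, _MW_MEAN) / 100.0,
            ],
        ]
    )


def _validate_sequence(sequence: str) -> str:
    sequence = sequence.strip().upper()
    if not sequence:
        raise ValueError("empty protein sequence")
    bad = sorted(set(sequence) - set(_ALPHABET))
    if bad:
        raise ValueError(f"sequence contains characters outside the amino-acid alphabet: {bad}")
    return sequence


def sequence_feature_matrix(sequence: str) -> np.ndarray:
    """L x F residue descriptor matrix for a validated sequence."""
    sequence = _validate_sequence(sequence)
    return np.stack([residue_descriptor(aa) for aa in sequence])


@dataclass
class ResidueContactGraph:
    sequence: str
    node_features: np.ndarray  # L x F_r
    edge_index: np.ndarray  # E x 2 directed pairs, symmetric
    edge_weights: np.ndarray  # contact probability per directed edge, in (0.5, 1]

    @property
    def num_nodes(self) -> int:
        return len(self.sequence)

    def adjacency(self) -> np.ndarray:
        """Dense symmetric weighted adjacency (probabilities; no self-loops); cached."""
        cached = getattr(self, "_adj", None)
        if cached is None:
            n = self.num_nodes
            cached = np.zeros((n, n))
            if len(self.edge_index):
                cached[self.edge_index[:, 0], self.edge_index[:, 1]] = self.edge_weights
            self._adj = cached
        return cached


@dataclass
class SequenceEmbedding:
    vector: np.ndarray

    @property
    def dim(self) -> int:
        return self.vector.shape[0]


@dataclass
class ProteinRep:
    """Both protein views for one target."""

    contact_graph: ResidueContactGraph
    sequence_embedding: SequenceEmbedding
    metadata: dict = field(default_factory=dict)


def build_contact_graph(
    sequence: str,
    contact_probs: np.ndarray,
    threshold: float = CONTACT_THRESHOLD,
) -> ResidueContactGraph:
    """Threshold a contact-probability matrix into a weighted residue graph.

    The matrix is max-symmetrized first (providers are not guaranteed to
    be exactly symmetric), then an edge (i, j), i != j, is created wherever
    the probability *strictly* exceeds `threshold`; the probability is the
    edge weight. Probabilities at exactly the threshold produce no edge.
    """
    sequence = _validate_sequence(sequence)
    probs = np.asarray(contact_probs, dtype=float)
    L = len(sequence)
    if probs.ndim != 2 or probs.shape[0] != probs.shape[1]:
        raise ValueError(f"contact matrix must be square, got shape {probs.shape}")
    if probs.shape[0] != L:
        raise ValueError(f"contact matrix size {probs.shape[0]} != sequence length {L}")
    if probs.size and (probs.min() < 0.0 or probs.max() > 1.0):
        raise ValueError("contact probabilities must lie in [0, 1]")

    sym = np.maximum(probs, probs.T)
    ii, jj = np.where(sym > threshold)
    keep = ii != jj
    ii, jj = ii[keep], jj[keep]
    edge_index = np.column_stack([ii, jj]) if len(ii) else np.zeros((0, 2), dtype=int)
    edge_weights = sym[ii, jj] if len(ii) else np.zeros(0)
    return ResidueContactGraph(
        sequence=sequence,
        node_features=sequence_feature_matrix(sequence),
        edge_index=edge_index,
        edge_weights=edge_weights,
    )


def pool_sequence_embedding(residue_embs: np.ndarray) -> SequenceEmbedding:
    """Average residue-level embeddings over positions (column-wise mean)."""
    residue_embs = np.asarray(residue_embs, dtype=float)
    if residue_embs.ndim != 2 or residue_embs.shape[0] < 1:
        raise ValueError(f"expected an L x E matrix with L >= 1, got shape {residue_embs.shape}")
    return SequenceEmbedding(vector=residue_embs.mean(axis=0))


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping."""
    return {record.id: str(record.seq).upper() for record in SeqIO.parse(str(path), "fasta")}
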