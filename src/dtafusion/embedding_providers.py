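"""Pluggable pre-trained embedding providers with deterministic offline fallbacks.

The model consumes two provider contracts and never knows which concrete
implementation it got:

* an **atom embedding provider** maps a molecule to an N x dim matrix of
  initial atom features (dim = 32 for the pre-trained molecular model
  this mirrors);
* a **protein embedding provider** maps a sequence to (L x dim residue
  embeddings, L x L contact probabilities) (dim = 1280 for the
  pre-trained protein language model this mirrors).

The fallback implementations shipped here are fully offline and
deterministic: embeddings are hashed from local chemical/residue
descriptors, and the synthetic contact matrix combines a near-diagonal
backbone band with sparse planted long-range contacts. Real pre-trained
adapters can be registered behind the same contracts; they are optional
extras and are not required by anything in the core package.

Because fallback residue embeddings are dominated by residue identity
(a small position-dependent perturbation is added on top), the pooled
sequence embedding is approximately a composition profile — a coarse
stand-in for the composition/evolutionary signal a real sequence model
exposes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .chem_graphs import Molecule

__all__ = [
    "AtomEmbeddingProvider",
    "ProteinEmbeddingProvider",
    "FallbackAtomProvider",
    "FallbackProteinProvider",
    "fallback_atom_embeddings",
    "fallback_protein_embeddings",
    "ATOM_EMBEDDING_DIM",
    "PROTEIN_EMBEDDING_DIM",
    "PROTEIN_SEQUENCE_LIMIT",
]

ATOM_EMBEDDING_DIM = 32
PROTEIN_EMBEDDING_DIM = 1280
# residue limit of the transformer protein model the adapter contract mirrors
PROTEIN_SEQUENCE_LIMIT = 1022


def _hash_rng(*parts) -> np.random.Generator:
    """Deterministic generator keyed by a stable hash of `parts`."""
    digest = hashlib.sha256("|".join(map(str, parts)).encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def fallback_atom_embeddings(mol: Molecule, dim: int = ATOM_EMBEDDING_DIM, seed: int = 0) -> np.ndarray:
    """Deterministic N x dim atom features hashed from local atom environments.

    Row i depends only on atom i's (element, degree, aromaticity, formal
    charge) and the seed, so chemically equivalent atoms — same local
    descriptor — receive identical rows, and repeated calls are
    bit-identical.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rows = np.zeros((mol.num_atoms, dim))
    for i, atom in enumerate(mol.atoms):
        rng = _hash_rng("atom", atom.element, atom.degree, atom.aromatic, atom.formal_charge, seed)
        rows[i] = rng.standard_normal(dim)
    return rows


def fallback_protein_embeddings(
    sequence: str,
    dim: int = PROTEIN_EMBEDDING_DIM,
    seed: int = 0,
    positional_scale: float = 0.1,
    band_width: int = 2,
    long_range_rate: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic residue embeddings + synthetic contact probabilities.

    Embedding row i = base(residue identity) + `positional_scale` *
    noise(position, sequence, seed): composition dominates, position
    perturbs. The contact matrix is symmetric with entries in [0, 1]:
    within `band_width` of the diagonal probabilities are drawn from
    (0.5, 1] (backbone-neighbour band), long-range pairs exceed 0.5 with
    probability `long_range_rate`, and everything else stays below 0.5.
    """
    if not sequence:
        raise ValueError("empty protein sequence")
    sequence = sequence.upper()
    L = len(sequence)
    emb = np.zeros((L, dim))
    for i, aa in enumerate(sequence):
        base = _hash_rng("res", aa, seed).standard_normal(dim)
        pos = _hash_rng("pos", i, sequence, seed).standard_normal(dim)
        emb[i] = base + positional_scale * pos

    # build the strict upper triangle, then mirror, so each unordered
    # long-range pair is an independent Bernoulli(long_range_rate) event
    rng = _hash_rng("contacts", sequence, seed)
    upper = np.triu(rng.uniform(0.0, 0.45, size=(L, L)), k=1)
    ii, jj = np.triu_indices(L, k=1)
    far = (jj - ii) > band_width
    planted = far & (rng.random(len(ii)) < long_range_rate)
    upper[ii[planted], jj[planted]] = rng.uniform(0.55, 1.0, size=int(planted.sum()))
    near = ~far
    upper[ii[near], jj[near]] = rng.uniform(0.55, 0.95, size=int(near.sum()))
    probs = upper + upper.T
    np.fill_diagonal(probs, 1.0)
    return emb, probs


@dataclass
class FallbackAtomProvider:
    """Offline atom-embedding provider built on descriptor hashing."""

    dim: int = ATOM_EMBEDDING_DIM
    seed: int = 0
    name: str = "fallback-atom"

    def __call__(self, mol: Molecule) -> np.ndarray:
        return self.embed(mol)

    def embed(self, mol: Molecule) -> np.ndarray:
        return fallback_atom_embeddings(mol, dim=self.dim, seed=self.seed)


@dataclass
class FallbackProteinProvider:
    """Offline protein provider: residue embeddings + synthetic contacts."""

    dim: int = PROTEIN_EMBEDDING_DIM
    seed: int = 0
    long_range_rate: float = 0.02
    band_width: int = 2
    max_length: int = PROTEIN_SEQUENCE_LIMIT
    name: str = "fallback-protein"
    _cache: dict = field(default_factory=dict, repr=False)

    def embed(self, sequence: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (L x dim residue embeddings, L x L contact probabilities).

        Sequences beyond `max_length` are truncated at the limit; the
        truncation is visible through :meth:`truncated_length`.
        """
        sequence = sequence.upper()
        if len(sequence) > self.max_length:
            sequence = sequence[: self.max_length]
        if sequence not in self._cache:
            self._cache[sequence] = fallback_protein_embeddings(
                sequence,
                dim=self.dim,
                seed=self.seed,
                band_width=self.band_width,
                long_range_rate=self.long_range_rate,
            )
        return self._cache[sequence]

    def truncated_length(self, sequence: str) -> int:
        return min(len(sequence), self.max_length)


# The contracts are structural: anything with the same call signatures
# (and deterministic output) is a valid provider.
AtomEmbeddingProvider = FallbackAtomProvider
ProteinEmbeddingProvider = FallbackProteinProvider
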