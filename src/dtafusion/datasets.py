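"""Benchmark readers, interaction-pair readers, and the synthetic benchmark generator.

The affinity-benchmark layout follows the convention the standard DTA
benchmarks (Davis, KIBA) are distributed in: a ligand table mapping
compound IDs to SMILES (JSON), a protein table mapping target IDs to
sequences (JSON), and a dense drug x target affinity matrix (whitespace-
delimited text) in which missing measurements are NaN. Davis affinities
are transformed to ``pKd = -log10(Kd / 1e9)`` at load time, the
convention of the model lineage this package follows.

The synthetic generator emulates that layout with a *plantable*
structure-to-affinity signal::

    affinity = base + alpha * frag(drug) + beta * motif(protein)
             + gamma * [frag(drug) > 0 and motif(protein) > 0] + noise

where ``frag`` counts a designated substructure (default: pyridine-type
aromatic rings) and ``motif`` counts a planted sequence 4-mer. The
interaction term gamma is recoverable only by a model that uses both
entities, which is what makes the benchmark a meaningful learning probe.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .protein_graphs import AMINO_ACIDS
from .training_eval import AffinityRecord, InteractionRecord

__all__ = [
    "DTADataset",
    "SyntheticConfig",
    "load_dta_dataset",
    "save_dta_dataset",
    "load_dpi_pairs",
    "davis_transform",
    "generate_synthetic_molecules",
    "generate_synthetic_proteins",
    "generate_synthetic_benchmark",
    "fragment_count",
    "motif_count",
]


@dataclass
class DTADataset:
    """One affinity benchmark: entity tables + dense affinity matrix."""

    ligands: dict[str, str]  # compound_id -> SMILES
    proteins: dict[str, str]  # target_id -> sequence
    affinity: np.ndarray  # drugs x targets, NaN marks missing
    name: str = "dataset"
    meta: dict = field(default_factory=dict)

    @property
    def records(self) -> list[AffinityRecord]:
        drug_ids = list(self.ligands)
        target_ids = list(self.proteins)
        recs = []
        for i, did in enumerate(drug_ids):
            for j, tid in enumerate(target_ids):
                y = self.affinity[i, j]
                if np.isfinite(y):
                    recs.append(AffinityRecord(drug_id=did, target_id=tid, affinity=float(y)))
        return recs


def davis_transform(kd_nm: np.ndarray) -> np.ndarray:
    """Kd in nM -> pKd = -log10(Kd / 1e9)."""
    return -np.log10(np.asarray(kd_nm, dtype=float) / 1e9)


def load_dta_dataset(directory: str | Path, name: str = "dataset") -> DTADataset:
    """Load the benchmark layout: ligands.json, proteins.json, affinity.txt.

    A dataset named ``davis`` (case-insensitive) has its raw Kd values
    transformed to pKd. Missing cells are NaN.
    """
    directory = Path(directory)
    lig_path = directory / "ligands.json"
    prot_path = directory / "proteins.json"
    aff_path = directory / "affinity.txt"
    for path, label in ((lig_path, "ligand table"), (prot_path, "protein table"), (aff_path, "affinity matrix")):
        if not path.exists():
            raise FileNotFoundError(f"missing {label}: {path}")
    ligands = json.loads(lig_path.read_text())
    proteins = json.loads(prot_path.read_text())
    affinity = np.loadtxt(aff_path, ndmin=2)
    if affinity.shape != (len(ligands), len(proteins)):
        raise ValueError(
            f"affinity matrix shape {affinity.shape} does not match "
            f"{len(ligands)} ligands x {len(proteins)} proteins"
        )
    if name.lower() == "davis":
        affinity = davis_transform(affinity)
    return DTADataset(ligands=ligands, proteins=proteins, affinity=affinity, name=name)


def save_dta_dataset(dataset: DTADataset, directory: str | Path) -> Path:
    """Write a dataset in the benchmark layout (inverse of the loader)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "ligands.json").write_text(json.dumps(dataset.ligands, indent=1))
    (directory / "proteins.json").write_text(json.dumps(dataset.proteins, indent=1))
    np.savetxt(directory / "affinity.txt", dataset.affinity)
    return directory


def load_dpi_pairs(
    path: str | Path,
    neg_ratio: float | None = None,
    seed: int = 0,
    sep: str | None = None,
) -> list[InteractionRecord]:
    """Read delimited (SMILES, sequence, 0/1 label) interaction pairs.

    `neg_ratio` re-samples negatives to `neg_ratio` negatives per
    positive (e.g. 3.0 for a 1:3 positive:negative ratio); an exact
    subsample is required, so too few negatives is an error.
    """
    df = pd.read_csv(path, sep=sep if sep is not None else r"\s+", header=None, engine="python")
    if df.shape[1] < 3:
        raise ValueError(f"expected 3 columns (SMILES, sequence, label), got {df.shape[1]}")
    df.columns = ["smiles", "sequence", "label"] + [f"extra{i}" for i in range(df.shape[1] - 3)]
    labels = df["label"].astype(int)
    if set(labels.unique()) - {0, 1}:
        raise ValueError("labels must be 0/1")
    pos = df[labels == 1]
    neg = df[labels == 0]
    if neg_ratio is not None:
        wanted = int(round(neg_ratio * len(pos)))
        if wanted > len(neg):
            raise ValueError(f"ratio 1:{neg_ratio} needs {wanted} negatives, only {len(neg)} available")
        neg = neg.sample(n=wanted, random_state=seed)
    keep = pd.concat([pos, neg])
    return [
        InteractionRecord(drug_id=row.smiles, target_id=row.sequence, label=int(row.label))
        for row in keep.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# synthetic benchmark
# ---------------------------------------------------------------------------

_RING_FRAGMENTS = ["c1ccccc1", "C1CCCCC1", "c1ccoc1", "C1CCNCC1", "c1ccsc1"]
_SIGNAL_RING = "c1ccncc1"  # pyridine: the designated affinity-carrying fragment
_CHAIN_ATOMS = ["C", "N", "O"]


@dataclass
class SyntheticConfig:
    """Study conditions for the planted-signal benchmark."""

    n_drugs: int = 200
    n_proteins: int = 50
    ring_prob: float = 0.6  # fraction of molecules carrying >= 1 ring
    signal_ring_prob: float = 0.5  # chance a ring-bearing molecule's ring is the signal fragment
    chain_len: tuple[int, int] = (1, 6)
    seq_len: tuple[int, int] = (30, 80)
    motif: str = "WHWKHWCW"
    motif_prob: float = 0.5  # fraction of proteins with the motif planted
    base: float = 5.0
    alpha: float = 0.5  # per designated-fragment increment
    beta: float = 0.8  # per motif-copy increment
    gamma: float = 1.0  # fragment AND motif interaction bonus
    noise_sd: float = 0.3
    missing_frac: float = 0.0
    pair_subsample: int | None = None  # keep at most this many non-missing cells
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 1 or self.n_proteins < 1:
            raise ValueError("entity counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _random_molecule(rng: np.random.Generator, config: SyntheticConfig) -> str:
    """One random SMILES: optional ring(s) + an acyclic chain with branches."""
    parts: list[str] = []
    if rng.random() < config.ring_prob:
        ring = _SIGNAL_RING if rng.random() < config.signal_ring_prob else str(rng.choice(_RING_FRAGMENTS))
        parts.append(ring)
        if rng.random() < 0.2:  # occasional second ring
            parts.append(str(rng.choice(_RING_FRAGMENTS + [_SIGNAL_RING])))
    n_chain = int(rng.integers(config.chain_len[0], config.chain_len[1] + 1))
    chain = ""
    prev = ""
    can_branch = False
    for _ in range(n_chain):
        atom = str(rng.choice(_CHAIN_ATOMS, p=[0.7, 0.15, 0.15]))
        # a branch adds a third bond to the branch point, which only C
        # (and singly: N) can carry; never branch the same atom twice
        if can_branch and prev == "C" and rng.random() < 0.2:
            chain += f"({atom})"
            can_branch = False
        else:
            chain += atom
            prev = atom
            can_branch = True
    parts.append(chain)
    smiles = "".join(parts)  # concatenation = single-bond linkage in SMILES
    assert Chem.MolFromSmiles(smiles) is not None, f"grammar produced invalid SMILES {smiles!r}"
    return smiles


def generate_synthetic_molecules(config: SyntheticConfig, n: int | None = None) -> list[str]:
    """Random parseable SMILES mixing ring-bearing and acyclic molecules."""
    rng = np.random.default_rng(config.seed)
    return [_random_molecule(rng, config) for _ in range(n if n is not None else config.n_drugs)]


def generate_synthetic_proteins(config: SyntheticConfig, n: int | None = None) -> list[str]:
    """Random sequences over the 20-letter alphabet; motif planted in a fraction."""
    rng = np.random.default_rng(config.seed + 1)
    aas = list(AMINO_ACIDS)
    seqs = []
    for _ in range(n if n is not None else config.n_proteins):
        L = int(rng.integers(config.seq_len[0], config.seq_len[1] + 1))
        seq = "".join(rng.choice(aas, size=L))
        if rng.random() < config.motif_prob:
            pos = int(rng.integers(0, L - len(config.motif) + 1))
            seq = seq[:pos] + config.motif + seq[pos + len(config.motif):]
        seqs.append(seq)
    return seqs


def fragment_count(smiles: str, smarts: str = _SIGNAL_RING) -> int:
    """Distinct atom-set matches of the designated fragment in a molecule."""
    mol = Chem.MolFromSmiles(smiles)
    patt = Chem.MolFromSmarts(smarts)
    if mol is None or patt is None:
        raise ValueError(f"cannot match {smarts!r} against {smiles!r}")
    return len({frozenset(m) for m in mol.GetSubstructMatches(patt)})


def motif_count(sequence: str, motif: str) -> int:
    return sequence.count(motif)


def synthetic_affinity(
    frag: int, motif: int, config: SyntheticConfig, noise: float = 0.0
) -> float:
    """The generative affinity formula (noise passed in explicitly)."""
    return (
        config.base
        + config.alpha * frag
        + config.beta * motif
        + config.gamma * float(frag > 0 and motif > 0)
        + noise
    )


def generate_synthetic_benchmark(config: SyntheticConfig) -> DTADataset:
    """Planted-signal benchmark in the standard affinity-matrix layout.

    The per-cell affinity needs the drug's fragment count, the protein's
    motif count, *and* their interaction, so only a model consuming both
    entities can recover the full signal. `missing_frac` blanks cells to
    NaN; `pair_subsample` keeps a random subset of cells (the rest become
    missing), emulating sparsely measured benchmarks.
    """
    rng = np.random.default_rng(config.seed + 2)
    smiles = generate_synthetic_molecules(config)
    seqs = generate_synthetic_proteins(config)
    frag = np.array([fragment_count(s) for s in smiles])
    mot = np.array([motif_count(p, config.motif) for p in seqs])

    noise = rng.normal(0.0, config.noise_sd, size=(config.n_drugs, config.n_proteins))
    inter = (frag[:, None] > 0) & (mot[None, :] > 0)
    affinity = (
        config.base
        + config.alpha * frag[:, None]
        + config.beta * mot[None, :]
        + config.gamma * inter.astype(float)
        + noise
    )
    if config.missing_frac > 0:
        affinity[rng.random(affinity.shape) < config.missing_frac] = np.nan
    if config.pair_subsample is not None and config.pair_subsample < affinity.size:
        flat = np.flatnonzero(np.isfinite(affinity.ravel()))
        keep = set(rng.choice(flat, size=config.pair_subsample, replace=False).tolist())
        mask = np.array([i not in keep for i in range(affinity.size)]).reshape(affinity.shape)
        affinity = affinity.copy()
        affinity[mask] = np.nan

    ligands = {f"D{i:04d}": s for i, s in enumerate(smiles)}
    proteins = {f"T{i:04d}": s for i, s in enumerate(seqs)}
    return DTADataset(
        ligands=ligands,
        proteins=proteins,
        affinity=affinity,
        name="synthetic",
        meta={
            "fragment_smarts": _SIGNAL_RING,
            "motif": config.motif,
            "fragment_counts": frag.tolist(),
            "motif_counts": mot.tolist(),
            "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()},
        },
    )
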