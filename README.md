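# dtafusion

Multi-view graph learning for drug–target binding affinity (DTA) and
drug–protein interaction (DPI) prediction, for computational chemists
and ML practitioners who want an affinity model whose every stage —
molecular graph construction, protein contact graphs, attention
encoders, gated fusion, evaluation protocol — is inspectable, seeded,
and runnable offline on a laptop CPU.

## The model

A compound–protein pair is encoded from four views and fused:

* **atom–bond graph** — atoms as nodes, bonds as attributed edges
  (bond-type + stereo one-hots), encoded by multi-head graph attention
  (GAT) with the edge attributes biasing the attention logits:
  `e_ij = LeakyReLU(aᵀ[Wh_i ‖ Wh_j] + w_eᵀx_ij)`,
  `α_ij = softmax_j(e_ij)`, `h'_i = ReLU(Σ_j α_ij W h_j)`;
* **pharmacophore graph** — a coarse functional-unit view: each ring
  (SSSR) is one node, each remaining acyclic bond with its two atoms is
  one node, units adjacent iff they share an atom; same GAT encoder;
* **residue contact graph** — residues as nodes, an edge wherever the
  predicted contact probability strictly exceeds 0.5, weighted by that
  probability; encoded by weighted GCN layers
  `H' = ReLU(D̃^{-1/2}(A+I)D̃^{-1/2} H W)` followed by a GAT layer;
* **sequence embedding** — mean-pooled residue embeddings through an
  MLP.

Max-pooled graph embeddings are concatenated per side
(`D_com = D_struct ‖ D_pharma`, `P_com = P_struct ‖ P_seq`), projected
to a common width, and combined by a context-aware sigmoid gate

    weight = σ(W₂ ReLU(W₁ (D_com + P_com) + b₁) + b₂)
    embedding = D_com ⊙ weight + P_com ⊙ (1 − weight)

before an MLP head predicts the affinity (or an interaction
probability). Per-atom attribution maps (gradient-weighted activation
mapping over the final compound-GAT layer) explain which atoms drive a
prediction. Pre-trained molecule/protein embedders plug in behind a
provider contract; deterministic offline fallbacks are included, so
nothing requires a download. A planted-signal synthetic benchmark
generator exercises the full pipeline, including cold-start splits
(unseen drugs, unseen proteins, or both) and the standard DTA metric
suite (MSE, concordance index, rm², Pearson, Spearman; AUC/P/R/F1;
clustering probes). See `docs/methods.md` for the full model and design
account.

## Worked example

```python
import numpy as np
from dtafusion import (
    ModelConfig, DTAModel, build_mol_graph_pair,
    SyntheticConfig, generate_synthetic_benchmark,
    TrainConfig, featurize_entities, make_cold_split, train_model, evaluate_split,
)

pair = build_mol_graph_pair("CC(=O)Oc1ccccc1C(=O)O")  # aspirin
print("atoms:", pair.molecule.num_atoms,
      "| bonds:", pair.molecule.num_bonds,
      "| pharmacophore units:", pair.pharmacophore.num_nodes)

config = ModelConfig(hidden=32, heads=2, n_gat_layers=2, n_gcn_layers=1,
                     fusion_width=32, dropout=0.1, seed=0)
dataset = generate_synthetic_benchmark(SyntheticConfig(n_drugs=60, n_proteins=25,
                                                       pair_subsample=800, seed=7))
records = dataset.records
drugs, proteins = featurize_entities(dataset.ligands, dataset.proteins, config)
split = make_cold_split(records, "cold_protein", frac_test=0.2, seed=0)
model = DTAModel(config)
train_model(model, drugs, proteins, records, split,
            TrainConfig(epochs=20, batch_size=512, lr=3e-3, seed=0))
report = evaluate_split(model, drugs, proteins, records, split)
print({k: round(v, 3) for k, v in report.to_dict().items()})
```

prints

```
atoms: 13 | bonds: 13 | pharmacophore units: 8
{'mse': 0.177, 'ci': 0.787, 'rm2': 0.761, 'pearson': 0.908, 'spearman': 0.78}
```

Aspirin decomposes into 8 functional units (the benzene ring plus 7
acyclic bonds). The trained model is then evaluated on *proteins it
never saw during training* (a cold-protein split): a Pearson of 0.91 and
concordance index of 0.79 mean it recovered most of the planted
structure→affinity signal, including the part only reachable by reading
the protein sequence.

A CLI covers the same workflow from the shell:

```bash
dtafusion synth bench/ --n-drugs 60 --n-proteins 25 --seed 7
dtafusion split bench/ split.json --regime cold_protein --seed 0
dtafusion train bench/ ckpt/ --split-file split.json --epochs 20
dtafusion evaluate ckpt/ bench/
dtafusion screen ckpt/ library.smi target.fasta --top 10
dtafusion explain ckpt/ "c1ccncc1CC" target.fasta
```

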