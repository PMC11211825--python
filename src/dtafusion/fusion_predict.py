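"""Context-aware fusion, prediction heads, the assembled model, and atom attribution.

The model encodes a drug-target pair from four views:

* ``D_struct`` — max-pooled multi-head GAT encoding of the atom-bond graph;
* ``D_pharma`` — max-pooled GAT encoding of the pharmacophore graph;
* ``P_struct`` — max-pooled GCN/GCN/GAT encoding of the weighted residue
  contact graph (contact probabilities weight the GCN adjacency and bias
  the GAT attention logits);
* ``P_seq`` — MLP encoding of the pooled sequence-level embedding.

Compound and protein views are concatenated into ``D_com = D_struct ||
D_pharma`` and ``P_com = P_struct || P_seq``, linearly projected to a
common fusion width, and combined by a learned sigmoid gate::

    attention(x) = W2 ReLU(W1 x + b1) + b2
    weight       = Sigmoid(attention(D_com + P_com))
    embedding    = D_com * weight + P_com * (1 - weight)

so every fused coordinate is a convex combination of the two modalities,
with the mixing ratio chosen from the joint context. A plain
concatenation baseline replaces the gate when fusion is ablated. The
prediction head is an MLP: unbounded output for affinity regression, a
final sigmoid for interaction classification.

Atom attribution (Grad-AAM) follows the CAM family: channel-averaged
gradients of the output with respect to the final compound-GAT node
activations weight those activations, ReLU-clipped and max-normalized
to [0, 1] per molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ._autodiff import Tensor, as_tensor, stack_rows
from .chem_graphs import (
    ATOM_DESCRIPTOR_DIM,
    BOND_FEATURE_DIM,
    PHARM_FEATURE_DIM,
    MolGraphPair,
    build_atom_bond_graph,
    build_pharmacophore_graph,
    parse_smiles,
)
from .embedding_providers import (
    ATOM_EMBEDDING_DIM,
    PROTEIN_EMBEDDING_DIM,
    FallbackAtomProvider,
    FallbackProteinProvider,
)
from .encoders import GATLayer, GCNLayer, Linear, MLP, Module, max_pool_readout
from .protein_graphs import (
    RESIDUE_DESCRIPTOR_DIM,
    ProteinRep,
    SequenceEmbedding,
    build_contact_graph,
    pool_sequence_embedding,
    sequence_feature_matrix,
)

__all__ = [
    "FusionContext",
    "FusionParams",
    "FusionBlock",
    "ModelConfig",
    "DTAModel",
    "fusion_gate",
    "fuse",
    "predict_affinity",
    "predict_interaction",
    "grad_aam",
    "UnsupportedAttributionError",
    "featurize_drug",
    "featurize_protein",
]


class UnsupportedAttributionError(RuntimeError):
    """Raised when attribution is requested for a view it cannot cover."""


@dataclass
class FusionContext:
    """All per-pair vectors produced on the way to one fused embedding."""

    D_struct: np.ndarray
    D_pharma: np.ndarray | None
    P_struct: np.ndarray
    P_seq: np.ndarray
    D_com: np.ndarray
    P_com: np.ndarray
    weight: np.ndarray | None  # None under the concatenation baseline
    embedding: np.ndarray


@dataclass
class FusionParams:
    """Projections to the common width plus the two-layer attention net."""

    proj_d: Linear
    proj_p: Linear
    W1: Tensor
    b1: Tensor
    W2: Tensor
    b2: Tensor


def fusion_gate(D_com, P_com, params: FusionParams) -> Tensor:
    """Sigmoid gate from the joint context of both (projected) embeddings.

    Accepts single vectors or row-matrices of equal width; entries are
    strictly inside (0, 1).
    """
    x = as_tensor(D_com) + as_tensor(P_com)
    attention = (x @ params.W1 + params.b1).relu() @ params.W2 + params.b2
    return attention.sigmoid()


def fuse(D_com, P_com, weight) -> Tensor:
    """Coordinate-wise convex combination ``D*w + P*(1-w)``."""
    D_com, P_com, weight = as_tensor(D_com), as_tensor(P_com), as_tensor(weight)
    if D_com.shape != P_com.shape or D_com.shape != weight.shape:
        raise ValueError("fuse requires three equal-shape inputs")
    return D_com * weight + P_com * (1.0 - weight)


class FusionBlock(Module):
    def __init__(self, d_width: int, p_width: int, fusion_width: int, rng: np.random.Generator):
        hidden = max(fusion_width // 2, 1)
        self.params = FusionParams(
            proj_d=Linear(d_width, fusion_width, rng),
            proj_p=Linear(p_width, fusion_width, rng),
            W1=Linear(fusion_width, hidden, rng).weight,
            b1=Tensor(np.zeros(hidden), requires_grad=True),
            W2=Linear(hidden, fusion_width, rng).weight,
            b2=Tensor(np.zeros(fusion_width), requires_grad=True),
        )

    def __call__(self, D_com: Tensor, P_com: Tensor) -> tuple[Tensor, Tensor]:
        d = self.params.proj_d(D_com)
        p = self.params.proj_p(P_com)
        weight = fusion_gate(d, p, self.params)
        return fuse(d, p, weight), weight


def predict_affinity(embedding, head: MLP) -> Tensor:
    """Unbounded regression output (no final activation)."""
    return head(as_tensor(embedding))


def predict_interaction(embedding, head: MLP) -> Tensor:
    """Interaction probability: sigmoid of the same head's pre-activation."""
    return predict_affinity(embedding, head).sigmoid()


@dataclass
class ModelConfig:
    """Architecture and ablation switches.

    The three booleans reproduce the ablation ladder: the baseline
    (``Model-1``) uses neither the pharmacophore view, nor pre-trained
    feature initialization, nor the gated fusion (plain concatenation);
    each switch adds one component, and the full model enables all three.
    """

    task: str = "dta"  # "dta" | "dpi"
    hidden: int = 256
    heads: int = 4
    n_gat_layers: int = 3  # compound views
    n_gcn_layers: int = 2  # protein conformation stack (GCN depth before the GAT)
    dropout: float = 0.2
    fusion_width: int = 256
    use_pharm: bool = True
    use_providers: bool = True
    use_fusion: bool = True
    drug_only: bool = False  # diagnostic baseline: protein embedding zeroed out
    concat_last_gat: bool = True
    atom_emb_dim: int = ATOM_EMBEDDING_DIM
    protein_emb_dim: int = PROTEIN_EMBEDDING_DIM
    seed: int = 0

    @classmethod
    def ablation(cls, level: int, **overrides) -> "ModelConfig":
        """Ablation ladder: 1 = baseline ... 4 = full model."""
        if level not in (1, 2, 3, 4):
            raise ValueError("ablation level must be 1..4")
        return cls(
            use_pharm=level >= 2,
            use_providers=level >= 3,
            use_fusion=level >= 4,
            **overrides,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def featurize_drug(smiles: str, config: ModelConfig, atom_provider: FallbackAtomProvider | None = None) -> MolGraphPair:
    """Build both molecular views with provider- or descriptor-initialized atoms."""
    mol = parse_smiles(smiles)
    embedder = None
    if config.use_providers:
        embedder = atom_provider or FallbackAtomProvider(dim=config.atom_emb_dim, seed=config.seed)
    return MolGraphPair(
        molecule=mol,
        atom_bond=build_atom_bond_graph(mol, embedder),
        pharmacophore=build_pharmacophore_graph(mol),
    )


def featurize_protein(
    sequence: str,
    config: ModelConfig,
    protein_provider: FallbackProteinProvider | None = None,
) -> ProteinRep:
    """Build the contact graph and the pooled sequence embedding.

    The provider always supplies the contact probabilities (the graph
    topology is not ablated); `use_providers` only governs whether the
    sequence-level embedding comes from provider residue embeddings or
    from pooled handcrafted residue descriptors.
    """
    provider = protein_provider or FallbackProteinProvider(dim=config.protein_emb_dim, seed=config.seed)
    used_length = provider.truncated_length(sequence)
    residue_embs, contact_probs = provider.embed(sequence)
    graph = build_contact_graph(sequence[:used_length], contact_probs)
    if config.use_providers:
        seq_emb = pool_sequence_embedding(residue_embs)
    else:
        seq_emb = pool_sequence_embedding(sequence_feature_matrix(sequence[:used_length]))
    meta = {"truncated": used_length < len(sequence), "used_length": used_length}
    return ProteinRep(contact_graph=graph, sequence_embedding=seq_emb, metadata=meta)


class _GATStack(Module):
    """Stacked multi-head GAT encoder for one molecular view."""

    def __init__(self, in_dim: int, config: ModelConfig, rng: np.random.Generator, edge_dim: int | None):
        per_head = max(config.hidden // config.heads, 1)
        self.layers: list[GATLayer] = []
        width = in_dim
        for i in range(config.n_gat_layers):
            last = i == config.n_gat_layers - 1
            concat = True if not last else config.concat_last_gat
            layer = GATLayer(width, per_head, rng, heads=config.heads, edge_dim=edge_dim, concat_heads=concat)
            self.layers.append(layer)
            width = per_head * config.heads if concat else per_head
        self.out_dim = width

    def __call__(self, adj: np.ndarray, H, edge_mat: np.ndarray | None = None) -> Tensor:
        h = as_tensor(H)
        for layer in self.layers:
            h = layer(adj, h, edge_mat)
        return h


class _ProteinStack(Module):
    """Conformation encoder: multilayer GCN followed by one GAT layer.

    Contact probabilities weight the GCN adjacency; the GAT layer
    receives them again as an additive attention-logit bias.
    """

    def __init__(self, in_dim: int, config: ModelConfig, rng: np.random.Generator):
        per_head = max(config.hidden // config.heads, 1)
        self.gcn_layers: list[GCNLayer] = []
        width = in_dim
        for _ in range(config.n_gcn_layers):
            self.gcn_layers.append(GCNLayer(width, config.hidden, rng))
            width = config.hidden
        self.gat = GATLayer(width, per_head, rng, heads=config.heads, edge_dim=1, concat_heads=True)
        self.out_dim = per_head * config.heads

    def __call__(self, weighted_adj: np.ndarray, H) -> Tensor:
        from .encoders import gcn_layer, normalized_adjacency

        h = as_tensor(H)
        norm = normalized_adjacency(weighted_adj)
        for layer in self.gcn_layers:
            h = gcn_layer(norm, h, layer.params, pre_normalized=True)
        edge_mat = weighted_adj[:, :, None]  # probability as 1-dim edge attribute
        return self.gat(weighted_adj, h, edge_mat)


class DTAModel(Module):
    """Multi-view drug-target affinity / interaction model."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self._rng = rng

        atom_in = config.atom_emb_dim if config.use_providers else ATOM_DESCRIPTOR_DIM
        self.atom_encoder = _GATStack(atom_in, config, rng, edge_dim=BOND_FEATURE_DIM)
        d_width = self.atom_encoder.out_dim
        if config.use_pharm:
            self.pharm_encoder = _GATStack(PHARM_FEATURE_DIM, config, rng, edge_dim=None)
            d_width += self.pharm_encoder.out_dim
        else:
            self.pharm_encoder = None

        self.protein_encoder = _ProteinStack(RESIDUE_DESCRIPTOR_DIM, config, rng)
        seq_in = config.protein_emb_dim if config.use_providers else RESIDUE_DESCRIPTOR_DIM
        self.seq_mlp = MLP([seq_in, config.hidden, config.hidden // 2], rng, drop=config.dropout)
        p_width = self.protein_encoder.out_dim + config.hidden // 2

        if config.use_fusion:
            self.fusion = FusionBlock(d_width, p_width, config.fusion_width, rng)
            head_in = config.fusion_width
        else:
            self.fusion = None
            head_in = d_width + p_width
        self.head = MLP([head_in, config.hidden, config.hidden // 2, 1], rng, drop=config.dropout)

        # set by encode_drug, consumed by grad_aam
        self._last_atom_activations: Tensor | None = None

    # -- per-entity encoders -------------------------------------------
    def encode_drug(self, pair: MolGraphPair, atom_mask: np.ndarray | None = None) -> Tensor:
        """D_com for one compound (optionally with atom rows masked out)."""
        ab = pair.atom_bond
        feats = ab.node_features
        if atom_mask is not None:
            feats = feats * np.asarray(atom_mask, dtype=float)[:, None]
        nodes = self.atom_encoder(ab.adjacency(), Tensor(feats), ab.edge_feature_matrix())
        self._last_atom_activations = nodes
        d_struct = max_pool_readout(nodes)
        if self.pharm_encoder is None:
            return d_struct
        ph = pair.pharmacophore
        pharm_nodes = self.pharm_encoder(ph.adjacency(), Tensor(ph.node_features))
        d_pharma = max_pool_readout(pharm_nodes)
        from ._autodiff import concatenate

        return concatenate([d_struct, d_pharma], axis=0)

    def encode_protein(self, rep: ProteinRep) -> Tensor:
        """P_com for one target."""
        if self.config.drug_only:
            width = self.protein_encoder.out_dim + self.config.hidden // 2
            return Tensor(np.zeros(width))
        graph = rep.contact_graph
        p_struct = max_pool_readout(self.protein_encoder(graph.adjacency(), Tensor(graph.node_features)))
        p_seq = self.seq_mlp(Tensor(rep.sequence_embedding.vector))
        from ._autodiff import concatenate

        return concatenate([p_struct, p_seq], axis=0)

    # -- pair / batch forward ------------------------------------------
    def _fuse(self, D_com: Tensor, P_com: Tensor) -> tuple[Tensor, Tensor | None]:
        if self.fusion is not None:
            return self.fusion(D_com, P_com)
        from ._autodiff import concatenate

        axis = D_com.ndim - 1
        return concatenate([D_com, P_com], axis=axis), None

    def forward_pair(self, drug: MolGraphPair, protein: ProteinRep, atom_mask: np.ndarray | None = None) -> Tensor:
        embedding, _ = self._fuse(self.encode_drug(drug, atom_mask), self.encode_protein(protein))
        out = self.head(embedding)
        if self.config.task == "dpi":
            out = out.sigmoid()
        return out.reshape(1)[0] if out.ndim else out

    def forward_batch(
        self,
        drugs: list[MolGraphPair],
        proteins: list[ProteinRep],
        pairs: list[tuple[int, int]],
        return_embeddings: bool = False,
    ):
        """Predictions for (drug_index, protein_index) pairs.

        Each unique entity is encoded once; pair rows are gathered from
        the stacked entity encodings, so gradients accumulate across all
        pairs an entity participates in.
        """
        D = stack_rows([self.encode_drug(d) for d in drugs])
        P = stack_rows([self.encode_protein(p) for p in proteins])
        di = np.array([i for i, _ in pairs], dtype=int)
        pi = np.array([j for _, j in pairs], dtype=int)
        embedding, _ = self._fuse(D.gather_rows(di), P.gather_rows(pi))
        out, penultimate = self.head(embedding, return_penultimate=True)
        out = out.reshape(-1)
        if self.config.task == "dpi":
            out = out.sigmoid()
        if return_embeddings:
            return out, penultimate
        return out

    def context(self, drug: MolGraphPair, protein: ProteinRep) -> FusionContext:
        """All intermediate fusion vectors for one pair (numpy, for probes)."""
        ab = drug.atom_bond
        nodes = self.atom_encoder(ab.adjacency(), Tensor(ab.node_features), ab.edge_feature_matrix())
        d_struct = max_pool_readout(nodes)
        d_pharma = None
        if self.pharm_encoder is not None:
            ph = drug.pharmacophore
            d_pharma = max_pool_readout(self.pharm_encoder(ph.adjacency(), Tensor(ph.node_features)))
        D_com = self.encode_drug(drug)
        P_com = self.encode_protein(protein)
        graph = protein.contact_graph
        p_struct = max_pool_readout(self.protein_encoder(graph.adjacency(), Tensor(graph.node_features)))
        p_seq = self.seq_mlp(Tensor(protein.sequence_embedding.vector))
        embedding, weight = self._fuse(D_com, P_com)
        return FusionContext(
            D_struct=d_struct.data.copy(),
            D_pharma=None if d_pharma is None else d_pharma.data.copy(),
            P_struct=p_struct.data.copy(),
            P_seq=p_seq.data.copy(),
            D_com=D_com.data.copy(),
            P_com=P_com.data.copy(),
            weight=None if weight is None else weight.data.copy(),
            embedding=embedding.data.copy(),
        )

    # -- serialization --------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"param_{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(f"state has {len(state)} arrays, model has {len(params)} parameters")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"param_{i}"], dtype=float)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for param_{i}: {arr.shape} vs {p.data.shape}")
            p.data = arr


def grad_aam(model: DTAModel, drug: MolGraphPair, protein: ProteinRep, view: str = "atom_bond") -> np.ndarray:
    """Per-atom attribution scores in [0, 1] for one prediction.

    Channel-averaged gradients of the output with respect to the final
    compound-GAT node activations weight those activations; scores are
    ReLU-clipped and max-normalized so the top atom scores exactly 1
    (an all-zero map is returned unchanged in the degenerate case).
    """
    if view != "atom_bond":
        raise UnsupportedAttributionError(
            f"attribution is only supported for the atom_bond view, not {view!r}"
        )
    was_training = model.training
    model.eval()
    try:
        model.zero_grad()
        out = model.forward_pair(drug, protein)
        out.backward()
        nodes = model._last_atom_activations
        if nodes is None or nodes.grad is None:
            raise UnsupportedAttributionError("no gradient reached the atom-bond activations")
        alpha = nodes.grad.mean(axis=0)  # channel weights
        scores = np.maximum(nodes.data @ alpha, 0.0)
        peak = scores.max()
        return scores / peak if peak > 0 else scores
    finally:
        if was_training:
            model.train()
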