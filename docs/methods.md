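# Methods

## Model

`dtafusion` predicts the binding affinity of a compound–protein pair
(or, in classification mode, the probability that they interact) from
four learned views.

**Compound, atom level.** The atom–bond graph has atoms as nodes and
covalent bonds as symmetric directed edge pairs carrying a bond-type
one-hot (single/double/triple/aromatic) and a stereo one-hot. Node
features come either from an atom-embedding provider (default width 32)
or from a handcrafted descriptor (element one-hot over a versioned
15-symbol vocabulary, degree, aromaticity, formal charge, chirality
one-hot, ring flag). A stack of multi-head graph-attention (GAT) layers
encodes the graph; per head

    e_ij = LeakyReLU( aᵀ [W h_i ‖ W h_j] + w_eᵀ x_ij )
    α_ij = softmax_j(e_ij)   over N_i ∪ {i}
    h'_i = ReLU( Σ_j α_ij W h_j )

with heads concatenated on every layer (a final-layer averaging variant
is available). `x_ij` is the bond-attribute vector; its learned scalar
projection enters the attention logit before the LeakyReLU (the slope is
0.2). Neighborhoods include the node itself so isolated atoms are
well-defined. A column-wise max-pool over nodes yields `D_struct`.

**Compound, functional-unit level.** The pharmacophore graph coarsens
the molecule into units: every ring of the smallest set of smallest
rings is one node (fused systems become several nodes; a ring bond
shared by two SSSR rings is assigned to the first ring in order, so unit
bond sets partition the bond set), and every remaining acyclic bond,
with its two atoms, is one node. Isolated atoms get a degenerate
one-atom unit so every atom is covered. Units are adjacent exactly when
they share an atom. Unit features concatenate sums and means of member-
atom descriptors with bond-type counts and unit statistics
(atom count, bond count, ring flag) — invariant to atom order by
construction. The same GAT stack plus max-pool yields `D_pharma`.

**Protein, conformation.** Residues are nodes of a weighted contact
graph: the provider's contact-probability matrix is max-symmetrized and
an edge (i, j), i ≠ j, is kept where the probability *strictly* exceeds
0.5, with the probability as the edge weight. Node features are a
residue descriptor (one-hot over the 20 amino acids + X, Kyte–Doolittle
hydropathy, side-chain charge at neutral pH, a polarity flag, residue
mass / 100; X gets a zero one-hot with neutral defaults). The encoder is
a multilayer graph convolution followed by one GAT layer:

    H^{l+1} = ReLU( D̃^{-1/2} (A + I) D̃^{-1/2} H^l W^l )

where the contact probabilities enter `A` as weighted entries (and the
degree matrix accordingly), and the same probabilities additionally bias
the GAT attention logits. Max-pool yields `P_struct`. Backbone
neighbours get no special edges; they are connected only if their
contact probability passes the threshold.

**Protein, sequence.** Residue-level embeddings (provider width 1280 by
default) are mean-pooled over positions and passed through an MLP to
give `P_seq`. Sequences beyond the provider's length limit (1022 by
default, mirroring transformer protein language models) are truncated,
and the truncation is recorded in the representation's metadata.

**Fusion.** With `D_com = D_struct ‖ D_pharma` and
`P_com = P_struct ‖ P_seq`, learned linear projections bring both to a
common fusion width (the sum in the gate is otherwise shape-illegal;
the default width is 256), then

    attention(x) = W₂ ReLU(W₁ x + b₁) + b₂
    weight       = σ( attention(D_com + P_com) )
    embedding    = D_com ⊙ weight + P_com ⊙ (1 − weight)

so each fused coordinate is a convex combination of the two modalities
with a context-dependent mixing ratio strictly inside (0, 1). The
ablation baseline replaces this by plain concatenation `[D_com ‖ P_com]`.
One gate network exists per model instance. An MLP head (ReLU, dropout)
produces an unbounded affinity for regression; classification adds a
final sigmoid, so the interaction logit coincides with the regression
head's pre-activation when weights are shared.

**Ablation ladder.** Three switches reproduce the standard ablation
series: the baseline uses neither the pharmacophore view, nor provider
initialization, nor gated fusion; each subsequent configuration adds one
component, ending at the full model. A separate diagnostic flag
(`drug_only`) zeroes the protein embedding entirely; it exists for the
cold-start probes, not as part of the ladder. Provider ablation governs
feature initialization only — the contact-graph topology always comes
from the protein provider, since the graph itself is not an ablated
component.

## Embedding providers

Model code consumes two provider contracts (atom: molecule → N×dim
matrix; protein: sequence → (L×dim, L×L contacts)) and never knows the
concrete implementation. The shipped providers are deterministic offline
fallbacks:

* atom rows are hashed from the local descriptor (element, degree,
  aromaticity, charge) and a seed, so chemically equivalent atoms get
  identical rows;
* residue rows are `base(residue identity) + 0.1 · noise(position)`, so
  the mean-pooled sequence embedding is approximately a composition
  profile — a deliberate, coarse emulation of the composition and
  conservation signal a real sequence model exposes;
* synthetic contact matrices are symmetric in [0, 1] with a
  supra-threshold band within 2 of the diagonal and long-range contacts
  planted as independent Bernoulli(0.02) events per residue pair.

Adapters for real pre-trained models can be registered behind the same
contracts; nothing in the core package requires them.

## Training

Mini-batch Adam on mean-squared error (affinity) or cross-entropy
(interaction). Each batch encodes every distinct entity once and gathers
pair rows from the stacked entity encodings, so gradients accumulate
across all pairs an entity participates in. For regression the head's
output bias starts at the train-target mean, so early epochs fit
structure rather than the offset. Optional early stopping monitors a
validation split (for k-fold affinity protocols a fraction of the
training records can be carved out, since that protocol has no native
validation set); the best-on-validation parameters are restored.
Non-finite losses abort with a diagnostic. Documented default
hyperparameters (all overridable): hidden width 256, 3 GAT layers per
compound view, 4 heads (concatenated), dropout 0.2, batch 128, learning
rate 5e-4, up to 500 epochs with patience 50.

Splits: random k-fold (default 6) with fold sizes within one record;
a random 8:1:1 split; and three cold-start regimes that hold out
*entities* — unseen drugs, unseen proteins, or both. In the pair regime
only records whose drug *and* protein are held out form the test set;
records mixing a seen and an unseen entity are marked unused, which is
what makes the overlap invariants exact. Overlap is asserted on every
generated split.

## Metrics

* **CI** (concordance index): over all pairs with distinct true
  affinity, concordant predictions count 1, predicted ties 0.5, divided
  by the pair count; true ties are excluded. This is the DTA
  literature's ranking metric (sometimes expanded as "confidence
  interval" in that literature, which is a misnomer — the implementation
  here is the concordance index). Invariant under strictly monotone
  transforms of the predictions.
* **rm²**: `r²(1 − √|r² − r₀²|)` with `r²` the squared Pearson
  correlation and `r₀² = 1 − Σ(y − kŷ)²/Σ(y − ȳ)²` the through-origin
  fit (`k = Σyŷ/Σŷ²`). Undefined (error) for constant inputs.
* MSE / Pearson / Spearman, AUC / precision / recall / F1 at a 0.5
  threshold, and silhouette / Calinski–Harabasz / Davies–Bouldin for the
  embedding-clustering probe, all via NumPy/SciPy/scikit-learn. The
  clustering probe labels drug–target pairs positive/negative by
  thresholding affinity (threshold configurable; the probes here use the
  median).

Davis-convention affinities (Kd in nM) are transformed to
`pKd = −log₁₀(Kd/10⁹)` at load time.

## Synthetic benchmark

The generator emulates the Davis/KIBA layout (ligand table, protein
table, dense affinity matrix with NaN for missing cells) with a planted
structure→affinity signal:

    y = 5.0 + 0.5·frag(d) + 0.8·motif(p) + 1.0·[frag(d)>0 ∧ motif(p)>0] + ε,
    ε ~ N(0, 0.3²)

where `frag` counts pyridine-type aromatic rings (distinct substructure
atom sets) and `motif` counts copies of the 8-residue motif `WHWKHWCW`,
planted at a random position in half the proteins. Molecules come from a
small valence-safe grammar (ring fragments plus branched C/N/O chains;
60 % carry a ring, half of ring bearers carry the signal ring); 
sequences are uniform over the 20-letter alphabet, 30–80 residues. The
interaction term makes part of the signal recoverable only by a model
that reads *both* entities — shuffling the drug–protein pairing destroys
exactly that variance component, which is tested by a regression-gain
oracle.

The motif length and effect size were set by a recoverability analysis:
with 50 proteins, a planted 4-mer shifts the pooled composition
embedding by well under the between-protein composition noise (a ridge
probe recovers essentially nothing), while an 8-mer is reliably
recoverable. The generator's planted signal is meant to be learnable at
the benchmark's own scale, so the 8-mer is the default.

What the generator does *not* emulate: real chemical series and
scaffolds, binding-site geometry, assay noise structure, the affinity
distributions of public benchmarks, or any correlation between molecule
size and affinity. Passing the learning probes therefore shows the
pipeline can extract a joint compound–protein signal end to end — not
that it reaches benchmark-level accuracy on real data.

## Problem sizes and probe protocol

The learning probes (acceptance tests and `scripts/acceptance.py`) use
200 drugs × 50 proteins with 2 500 sampled affinity cells, a scaled-down
architecture (hidden 32, 2 GAT layers, 2 heads, fusion width 32,
dropout 0.1) and 20 epochs of Adam (batch 512, lr 3e-3) — sizes chosen
so a full three-seed study runs on a single CPU in minutes. Three probes
run per seed: the full model, a control trained on permuted labels
(evaluated against true labels), and the drug-only baseline, all on
cold-protein splits with 20 % of proteins held out.

## Numerical choices

* All computation is float64 on a small reverse-mode autodiff engine
  written for this package; dense adjacency/attention matrices are used
  throughout (graphs here are small: molecules tens of atoms, proteins
  hundreds of residues).
* Softmax rows are shifted by their max before exponentiation; masked
  entries get −10³⁰ logits and exactly zero probability; empty rows
  yield zeros rather than NaN.
* Max-pool routes its subgradient to the first argmax on ties.
* Contact thresholding is strict (> 0.5); provider matrices are
  max-symmetrized *before* thresholding.
* Sigmoid inputs are clipped to ±500 to avoid overflow warnings.
* Degenerate clustering inputs (a cluster with fewer than 2 points, or
  all-identical embeddings) raise instead of returning sentinel values.

## Known limitations

* No sparse kernels: quadratic memory in nodes per graph caps practical
  protein length well below the provider truncation limit.
* No GPU path and no multi-device training; wall-clock scales linearly
  in entities per epoch.
* The offline providers carry no real pre-trained knowledge; conclusions
  about provider-driven generalization on real data require real
  adapters.
* The pharmacophore view is a ring/acyclic-bond coarsening, not
  pharmacophore perception in the docking sense (no HBD/HBA/aromatic
  feature typing).
* Attribution covers the atom-bond view only; pharmacophore and protein
  views have no gradient-attribution path.
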