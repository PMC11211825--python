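"""Dataset splitting, evaluation metrics, losses, and the training loop.

Metric conventions follow the affinity-prediction literature:

* **CI** (concordance index): over all sample pairs with distinct true
  affinity, the fraction whose predicted ordering agrees with the true
  ordering; predicted ties score 0.5, true ties are excluded.
* **rm2**: ``r2 * (1 - sqrt(|r2 - r0_sq|))`` where ``r2`` is the squared
  Pearson correlation (with intercept) and ``r0_sq`` the squared
  correlation of the least-squares fit through the origin — a penalty on
  predictions whose scale drifts even when they rank well.
* Regression additionally reports MSE, Pearson and Spearman;
  classification reports AUC, precision, recall and F1 at a threshold;
  clustering probes on penultimate-layer embeddings report silhouette,
  Calinski-Harabasz and Davies-Bouldin.

Split regimes: random k-fold, a random 8:1:1 split, and three cold-start
regimes that hold out entities rather than records — unseen drugs,
unseen proteins, or both (in which case pairs mixing a seen and an
unseen entity are set aside as unused, so the overlap invariants hold
exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _scipy_stats
from sklearn import metrics as _skmetrics

from ._autodiff import Tensor
from .fusion_predict import DTAModel, ModelConfig, featurize_drug, featurize_protein

__all__ = [
    "AffinityRecord",
    "InteractionRecord",
    "SplitSpec",
    "MetricReport",
    "TrainConfig",
    "TrainingDivergedError",
    "make_kfold_split",
    "make_random_split",
    "make_cold_split",
    "concordance_index",
    "rm2_metric",
    "regression_metrics",
    "classification_metrics",
    "clustering_metrics",
    "Adam",
    "mse_loss",
    "bce_loss",
    "featurize_entities",
    "train_model",
    "predict_records",
    "evaluate_split",
]


@dataclass(frozen=True)
class AffinityRecord:
    drug_id: str
    target_id: str
    affinity: float


@dataclass(frozen=True)
class InteractionRecord:
    drug_id: str
    target_id: str
    label: int


@dataclass
class SplitSpec:
    """Record-index -> {train, val, test, unused} assignment with a declared regime."""

    regime: str
    assignments: dict[int, str]
    seed: int

    def indices(self, part: str) -> list[int]:
        return sorted(i for i, p in self.assignments.items() if p == part)

    @property
    def train(self) -> list[int]:
        return self.indices("train")

    @property
    def val(self) -> list[int]:
        return self.indices("val")

    @property
    def test(self) -> list[int]:
        return self.indices("test")


@dataclass
class MetricReport:
    mse: float | None = None
    ci: float | None = None
    rm2: float | None = None
    pearson: float | None = None
    spearman: float | None = None
    auc: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    sc: float | None = None
    chi: float | None = None
    dbi: float | None = None

    def to_dict(self) -> dict[str, float]:
        return {k: v for k, v in vars(self).items() if v is not None}


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def make_kfold_split(records: Sequence, k: int = 6, seed: int = 0) -> list[SplitSpec]:
    """Seeded k-fold rotation; fold sizes differ by at most one record."""
    n = len(records)
    if n < k:
        raise ValueError(f"need at least k={k} records, got {n}")
    perm = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(perm, k)
    specs = []
    for f in range(k):
        assignments = {int(i): "train" for i in perm}
        for i in folds[f]:
            assignments[int(i)] = "test"
        specs.append(SplitSpec(regime=f"kfold{k}", assignments=assignments, seed=seed))
    return specs


def make_random_split(records: Sequence, fractions=(0.8, 0.1, 0.1), seed: int = 0) -> SplitSpec:
    """Random train/val/test record split (default 8:1:1)."""
    n = len(records)
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    assignments: dict[int, str] = {}
    for pos, i in enumerate(perm):
        part = "train" if pos < n_train else ("val" if pos < n_train + n_val else "test")
        assignments[int(i)] = part
    return SplitSpec(regime="split811", assignments=assignments, seed=seed)


def make_cold_split(
    records: Sequence,
    mode: str,
    frac_test: float = 0.2,
    seed: int = 0,
    frac_val: float = 0.0,
) -> SplitSpec:
    """Entity-level holdout split.

    ``cold_drug`` holds out a fraction of drugs, ``cold_protein`` a
    fraction of proteins, ``cold_pair`` both — in the pair regime only
    records where *both* entities are unseen form the test set, and
    records mixing a held-out entity with a training entity are marked
    ``unused`` so the overlap invariants hold exactly.
    """
    if mode not in ("cold_drug", "cold_protein", "cold_pair"):
        raise ValueError(f"unknown cold-start mode {mode!r}")
    rng = np.random.default_rng(seed)
    drugs = sorted({r.drug_id for r in records})
    prots = sorted({r.target_id for r in records})

    def holdout(entities: list[str]) -> set[str]:
        n_test = int(round(frac_test * len(entities)))
        if n_test < 1 or n_test >= len(entities):
            raise ValueError(
                f"frac_test={frac_test} infeasible for {len(entities)} entities"
            )
        return set(rng.choice(entities, size=n_test, replace=False))

    test_drugs = holdout(drugs) if mode in ("cold_drug", "cold_pair") else set()
    test_prots = holdout(prots) if mode in ("cold_protein", "cold_pair") else set()

    assignments: dict[int, str] = {}
    for i, r in enumerate(records):
        d_cold = r.drug_id in test_drugs
        p_cold = r.target_id in test_prots
        if mode == "cold_drug":
            assignments[i] = "test" if d_cold else "train"
        elif mode == "cold_protein":
            assignments[i] = "test" if p_cold else "train"
        else:
            if d_cold and p_cold:
                assignments[i] = "test"
            elif d_cold or p_cold:
                assignments[i] = "unused"
            else:
                assignments[i] = "train"

    if frac_val > 0:
        train_idx = [i for i, p in assignments.items() if p == "train"]
        n_val = int(round(frac_val * len(train_idx)))
        for i in rng.choice(train_idx, size=n_val, replace=False):
            assignments[int(i)] = "val"
    spec = SplitSpec(regime=mode, assignments=assignments, seed=seed)
    _assert_cold_invariants(records, spec, mode)
    return spec


def _assert_cold_invariants(records: Sequence, spec: SplitSpec, mode: str) -> None:
    train_ids = [records[i] for i in spec.train] + [records[i] for i in spec.val]
    test_ids = [records[i] for i in spec.test]
    if mode in ("cold_drug", "cold_pair"):
        overlap = {r.drug_id for r in train_ids} & {r.drug_id for r in test_ids}
        assert not overlap, f"cold split leaked drugs: {sorted(overlap)[:5]}"
    if mode in ("cold_protein", "cold_pair"):
        overlap = {r.target_id for r in train_ids} & {r.target_id for r in test_ids}
        assert not overlap, f"cold split leaked proteins: {sorted(overlap)[:5]}"


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def concordance_index(y_true, y_pred) -> float:
    """Pairwise ranking agreement in [0, 1]; predicted ties score 0.5."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or len(y_true) < 2:
        raise ValueError("concordance_index expects two equal-length 1-D arrays, n >= 2")
    dt = y_true[:, None] - y_true[None, :]
    dp = y_pred[:, None] - y_pred[None, :]
    # orient every informative pair (distinct true values) as (higher, lower)
    informative = np.triu(dt != 0, k=1)
    hi_first = informative & (dt > 0)
    lo_first = informative & (dt < 0)
    pred_diff = np.where(hi_first, dp, np.where(lo_first, -dp, np.nan))
    pairs = pred_diff[informative]
    if pairs.size == 0:
        raise ValueError("no pairs with distinct true values")
    score = np.where(pairs > 0, 1.0, np.where(pairs == 0, 0.5, 0.0))
    return float(score.mean())


def rm2_metric(y_true, y_pred) -> float:
    """``r2 * (1 - sqrt(|r2 - r0_sq|))`` with the through-origin ``r0_sq``."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or len(y_true) < 2:
        raise ValueError("rm2 expects two equal-length arrays, n >= 2")
    if np.allclose(y_pred, y_pred[0]) or np.allclose(y_true, y_true[0]):
        raise ValueError("rm2 undefined for constant inputs")
    r = float(np.corrcoef(y_true, y_pred)[0, 1])
    r2 = r * r
    k = float(np.dot(y_true, y_pred) / np.dot(y_pred, y_pred))
    ss_res0 = float(np.sum((y_true - k * y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r0_sq = 1.0 - ss_res0 / ss_tot
    return float(r2 * (1.0 - np.sqrt(abs(r2 - r0_sq))))


def regression_metrics(y_true, y_pred) -> MetricReport:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or len(y_true) < 2:
        raise ValueError("regression metrics expect equal-length arrays, n >= 2")
    report = MetricReport(mse=float(np.mean((y_true - y_pred) ** 2)))
    report.ci = concordance_index(y_true, y_pred)
    if not (np.allclose(y_pred, y_pred[0]) or np.allclose(y_true, y_true[0])):
        report.pearson = float(_scipy_stats.pearsonr(y_true, y_pred)[0])
        report.spearman = float(_scipy_stats.spearmanr(y_true, y_pred)[0])
        report.rm2 = rm2_metric(y_true, y_pred)
    return report


def classification_metrics(labels, probs, threshold: float = 0.5) -> MetricReport:
    labels = np.asarray(labels, dtype=int)
    probs = np.asarray(probs, dtype=float)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    preds = (probs >= threshold).astype(int)
    return MetricReport(
        auc=float(_skmetrics.roc_auc_score(labels, probs)),
        precision=float(_skmetrics.precision_score(labels, preds, zero_division=0)),
        recall=float(_skmetrics.recall_score(labels, preds, zero_division=0)),
        f1=float(_skmetrics.f1_score(labels, preds, zero_division=0)),
    )


def clustering_metrics(embeddings, labels) -> MetricReport:
    """Silhouette / Calinski-Harabasz / Davies-Bouldin on embedding vectors."""
    embeddings = np.asarray(embeddings, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2 or min(np.bincount(labels.astype(int))) < 2:
        raise ValueError("clustering metrics need >= 2 points in each of >= 2 clusters")
    if np.allclose(embeddings.var(axis=0), 0.0):
        raise ValueError("degenerate embeddings: zero variance in every dimension")
    return MetricReport(
        sc=float(_skmetrics.silhouette_score(embeddings, labels)),
        chi=float(_skmetrics.calinski_harabasz_score(embeddings, labels)),
        dbi=float(_skmetrics.davies_bouldin_score(embeddings, labels)),
    )


# ---------------------------------------------------------------------------
# optimization & training
# ---------------------------------------------------------------------------

class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite."""


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 5e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * p.grad
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * p.grad**2
            m_hat = self.m[i] / (1 - self.beta1**self.t)
            v_hat = self.v[i] / (1 - self.beta2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(np.asarray(target, dtype=float))
    return (diff * diff).mean()


def bce_loss(prob: Tensor, target: np.ndarray, eps: float = 1e-12) -> Tensor:
    y = np.asarray(target, dtype=float)
    p = prob
    return -((Tensor(y) * (p + eps).log() + Tensor(1.0 - y) * (1.0 - p + eps).log()).mean())


@dataclass
class TrainConfig:
    epochs: int = 500
    batch_size: int = 128
    lr: float = 5e-4
    patience: int = 50
    seed: int = 0
    val_fraction: float = 0.0  # carve this fraction of train records for early stopping


def featurize_entities(ligands: dict[str, str], proteins: dict[str, str], config: ModelConfig,
                       atom_provider=None, protein_provider=None):
    """Featurize every unique compound and target once, keyed by ID."""
    drug_graphs = {did: featurize_drug(smi, config, atom_provider) for did, smi in ligands.items()}
    protein_reps = {tid: featurize_protein(seq, config, protein_provider) for tid, seq in proteins.items()}
    return drug_graphs, protein_reps


def _index_entities(records: Sequence, indices: Iterable[int]):
    """Unique entity ID lists + per-record index pairs for a record subset."""
    idx = list(indices)
    drug_ids = sorted({records[i].drug_id for i in idx})
    prot_ids = sorted({records[i].target_id for i in idx})
    d_pos = {d: p for p, d in enumerate(drug_ids)}
    p_pos = {t: p for p, t in enumerate(prot_ids)}
    pairs = [(d_pos[records[i].drug_id], p_pos[records[i].target_id]) for i in idx]
    return drug_ids, prot_ids, pairs


def predict_records(model: DTAModel, drug_graphs: dict, protein_reps: dict,
                    records: Sequence, indices: Iterable[int],
                    return_embeddings: bool = False):
    """Eval-mode predictions (and optionally penultimate embeddings) for records."""
    idx = list(indices)
    drug_ids, prot_ids, pairs = _index_entities(records, idx)
    was_training = model.training
    model.eval()
    try:
        out = model.forward_batch(
            [drug_graphs[d] for d in drug_ids],
            [protein_reps[t] for t in prot_ids],
            pairs,
            return_embeddings=return_embeddings,
        )
    finally:
        if was_training:
            model.train()
    if return_embeddings:
        preds, emb = out
        return preds.data.copy(), emb.data.copy()
    return out.data.copy()


def train_model(
    model: DTAModel,
    drug_graphs: dict,
    protein_reps: dict,
    records: Sequence,
    split: SplitSpec,
    config: TrainConfig,
) -> dict:
    """Mini-batch Adam training with optional early stopping.

    Returns a history dict with per-epoch train (and val) losses; the
    model is left holding the best-on-validation parameters (final
    parameters when no validation split is used).
    """
    rng = np.random.default_rng(config.seed)
    task = model.config.task
    loss_fn = mse_loss if task == "dta" else bce_loss

    train_idx = list(split.train)
    val_idx = list(split.val)
    if not train_idx:
        raise ValueError("empty training split")
    if config.val_fraction > 0 and not val_idx:
        n_val = max(1, int(round(config.val_fraction * len(train_idx))))
        chosen = set(map(int, rng.choice(train_idx, size=n_val, replace=False)))
        val_idx = sorted(chosen)
        train_idx = [i for i in train_idx if i not in chosen]

    def target_of(i: int) -> float:
        r = records[i]
        return float(r.affinity if task == "dta" else r.label)

    if task == "dta":
        # start the head at the train-target mean so early epochs fit
        # structure rather than the offset
        out_bias = model.head.layers[-1].bias
        if out_bias is not None and np.allclose(out_bias.data, 0.0):
            out_bias.data = out_bias.data + float(np.mean([target_of(i) for i in train_idx]))

    optimizer = Adam(model.parameters(), lr=config.lr)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state: dict | None = None
    patience_left = config.patience

    model.train()
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_idx))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = [train_idx[j] for j in order[start : start + config.batch_size]]
            drug_ids, prot_ids, pairs = _index_entities(records, batch)
            model.zero_grad()
            preds = model.forward_batch(
                [drug_graphs[d] for d in drug_ids],
                [protein_reps[t] for t in prot_ids],
                pairs,
            )
            loss = loss_fn(preds, np.array([target_of(i) for i in batch]))
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(batch)
        history["train_loss"].append(epoch_loss / len(train_idx))

        if val_idx:
            val_preds = predict_records(model, drug_graphs, protein_reps, records, val_idx)
            val_targets = np.array([target_of(i) for i in val_idx])
            val_loss = float(np.mean((val_preds - val_targets) ** 2)) if task == "dta" else float(
                bce_loss(Tensor(val_preds), val_targets).data
            )
            history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_state = model.state_dict()
                patience_left = config.patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break

    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return history


def evaluate_split(model: DTAModel, drug_graphs: dict, protein_reps: dict,
                   records: Sequence, split: SplitSpec, part: str = "test") -> MetricReport:
    idx = split.indices(part)
    preds = predict_records(model, drug_graphs, protein_reps, records, idx)
    if model.config.task == "dta":
        targets = np.array([records[i].affinity for i in idx], dtype=float)
        return regression_metrics(targets, preds)
    targets = np.array([records[i].label for i in idx], dtype=int)
    return classification_metrics(targets, preds)
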