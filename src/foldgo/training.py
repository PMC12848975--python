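"""Data splitting, the multilabel training loop, and the estimator facade.

Training minimizes mean elementwise binary cross-entropy with Adam over
graph-level minibatches of proteins, tracks the validation Fmax every epoch,
restores the best-validation parameters, and stops early after a patience
window without improvement. :class:`GraphCbamGoClassifier` wraps the whole
model+training machinery in the scikit-learn estimator protocol (``fit`` /
``predict_proba`` / ``score``), so it composes with sklearn model-selection
utilities; the module-level functions are the underlying primitives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator

from . import model as M
from .metrics import fmax
from .structgraph import ContactGraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein's model inputs: graph, fused node features, sequence vector."""

    protein_id: str
    graph: ContactGraph
    features: np.ndarray       # N × in_dim fused features
    seq_embedding: np.ndarray  # (seq_dim,)
    _a_norm_cache: list = field(default_factory=list, repr=False, compare=False)

    def a_norm(self) -> np.ndarray:
        if not self._a_norm_cache:
            self._a_norm_cache.append(M.mean_adjacency(self.graph))
        return self._a_norm_cache[0]


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test partition specification (8:1:1 by default)."""

    ratios: tuple[float, float, float] = (8.0, 1.0, 1.0)
    seed: int = 0
    assignment: dict[str, str] | None = None

    def partition(self, part: str) -> list[str]:
        if self.assignment is None:
            raise ValueError("split has not been assigned yet")
        return [p for p, q in self.assignment.items() if q == part]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for the multilabel trainer."""

    epochs: int = 120
    batch_size: int = 32
    learning_rate: float = 1e-3
    early_stop_patience: int = 30
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    ema_decay: float = 0.98  # Polyak averaging of weights; 0 disables

    def __post_init__(self) -> None:
        for name in ("epochs", "batch_size", "early_stop_patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TrainHistory:
    """Per-epoch training loss and validation metric trace."""

    train_loss: list[float] = field(default_factory=list)
    val_fmax: list[float] = field(default_factory=list)
    best_epoch: int = -1


def split_data(protein_ids: list[str], spec: SplitSpec) -> SplitSpec:
    """Seeded shuffle then contiguous cut into train/val/test.

    Partition sizes follow largest-remainder rounding of the ratios, so a
    10-protein set at 8:1:1 splits exactly 8/1/1. Deterministic under
    ``spec.seed``.
    """
    ids = list(protein_ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 proteins to split")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]

    total = len(ids)
    ratios = np.asarray(spec.ratios, dtype=float)
    exact = ratios / ratios.sum() * total
    sizes = np.floor(exact).astype(int)
    remainder = exact - sizes
    for _ in range(total - sizes.sum()):
        j = int(np.argmax(remainder))
        sizes[j] += 1
        remainder[j] = -1.0
    sizes = np.maximum(sizes, 0)

    assignment: dict[str, str] = {}
    cursor = 0
    for part, size in zip(("train", "val", "test"), sizes):
        for pid in shuffled[cursor: cursor + size]:
            assignment[pid] = part
        cursor += size
    return replace(spec, assignment=assignment)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], config: TrainConfig):
        self.cfg = config
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        c = self.cfg
        bc1 = 1.0 - c.beta1 ** self.t
        bc2 = 1.0 - c.beta2 ** self.t
        for k, g in grads.items():
            m, v = self.m[k], self.v[k]
            m *= c.beta1
            m += (1 - c.beta1) * g
            v *= c.beta2
            v += (1 - c.beta2) * (g * g)
            params[k] -= c.learning_rate * (m / bc1) / (np.sqrt(v / bc2) + c.eps)


def predict(state: M.ModelState, dataset: list[ProteinRecord]) -> np.ndarray:
    """Deterministic forward pass per protein; rows align to dataset order."""
    if not dataset:
        return np.zeros((0, state.config.n_labels))
    out = np.empty((len(dataset), state.config.n_labels))
    for i, rec in enumerate(dataset):
        out[i] = M.forward(
            rec.graph, rec.features, rec.seq_embedding, state,
            a_norm=rec.a_norm(),
        )
    return out


def train(
    state: M.ModelState,
    dataset: list[ProteinRecord],
    labels: np.ndarray,
    config: TrainConfig,
    val_dataset: list[ProteinRecord] | None = None,
    val_labels: np.ndarray | None = None,
) -> tuple[M.ModelState, TrainHistory]:
    """Minibatch Adam training of the mean binary cross-entropy.

    Validation Fmax is tracked each epoch when a validation set is given;
    the best-validation parameters are restored at the end and training
    stops early after ``early_stop_patience`` epochs without improvement.
    Without a validation set the final parameters are returned.
    """
    labels = np.asarray(labels, dtype=float)
    if labels.shape != (len(dataset), state.config.n_labels):
        raise ValueError("label matrix is not aligned with the dataset")
    has_val = val_dataset is not None and val_labels is not None and len(val_dataset) > 0

    state = state.copy()
    optimizer = _Adam(state.params, config)
    rng = np.random.default_rng(config.seed)
    dropout_rng = (
        np.random.default_rng(config.seed + 1)
        if (state.config.classifier_dropout > 0.0
            or state.config.seq_dropout > 0.0)
        else None
    )
    # Polyak (exponential moving) average of the weights; validation and the
    # returned parameters use the averaged weights, which damps both
    # minibatch noise and checkpoint-selection noise on small datasets.
    use_ema = config.ema_decay > 0.0
    ema = {k: v.copy() for k, v in state.params.items()} if use_ema else None
    history = TrainHistory()
    best_state = state.copy()
    best_val = -np.inf
    stale = 0

    for epoch in range(config.epochs):
        order = rng.permutation(len(dataset))
        epoch_loss = 0.0
        for lo in range(0, len(order), config.batch_size):
            batch = order[lo: lo + config.batch_size]
            caches = []
            batch_loss = 0.0
            for i in batch:
                rec = dataset[i]
                probs, cache = M._forward_cached(
                    rec.graph, rec.features, rec.seq_embedding, state,
                    a_norm=rec.a_norm(), dropout_rng=dropout_rng,
                )
                batch_loss += M.bce_loss(probs, labels[i])
                caches.append(cache)

            # classifier gradients batched as matrix products over the
            # minibatch; graph-stage gradients stay per protein
            y_b = labels[batch]
            probs_b = np.stack([c["probs"] for c in caches])
            u_b = np.stack([c["u"] for c in caches])
            upre_b = np.stack([c["u_pre"] for c in caches])
            z_b = np.stack([c["z"] for c in caches])
            dlogits_b = (probs_b - y_b) / y_b.shape[1]
            dupre_b = (dlogits_b @ state.params["cls_W2"].T) * (upre_b > 0)
            dz_b = dupre_b @ state.params["cls_W1"].T
            grads: dict[str, np.ndarray] = {
                "cls_W2": u_b.T @ dlogits_b,
                "cls_b2": dlogits_b.sum(axis=0),
                "cls_W1": z_b.T @ dupre_b,
                "cls_b1": dupre_b.sum(axis=0),
            }
            for j, cache in enumerate(caches):
                dz = dz_b[j]
                if "dropout_mask" in cache:
                    dz = dz * cache["dropout_mask"]
                for k, g in M._backward_graph(cache, state, dz).items():
                    if k in grads:
                        grads[k] += g
                    else:
                        grads[k] = g
            scale = 1.0 / batch.size
            if not np.isfinite(batch_loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "lower the learning rate or inspect the inputs"
                )
            for g in grads.values():
                g *= scale
            optimizer.step(state.params, grads)
            if use_ema:
                d = config.ema_decay
                for k, e in ema.items():
                    e *= d
                    e += (1.0 - d) * state.params[k]
            epoch_loss += batch_loss
        history.train_loss.append(epoch_loss / len(dataset))
        eval_state = (
            M.ModelState(params=ema, config=state.config) if use_ema else state
        )

        if has_val:
            val_preds = predict(eval_state, val_dataset)
            vf, _ = fmax(val_preds, val_labels)
            history.val_fmax.append(vf)
            if vf > best_val:
                best_val = vf
                best_state = eval_state.copy()
                history.best_epoch = epoch
                stale = 0
            else:
                stale += 1
                if stale >= config.early_stop_patience:
                    logger.info("early stop at epoch %d (best %d)", epoch,
                                history.best_epoch)
                    break

    if has_val:
        return best_state, history
    history.best_epoch = len(history.train_loss) - 1
    return eval_state.copy() if use_ema else state, history


def naive_prevalence_predictions(
    train_labels: np.ndarray, n_proteins: int
) -> np.ndarray:
    """The naive baseline: every protein scores each term by its training
    prevalence."""
    prevalence = np.asarray(train_labels, dtype=float).mean(axis=0)
    return np.tile(prevalence, (n_proteins, 1))


def write_prediction_tsv(
    preds: np.ndarray, proteins: list[str], terms: list[str], path
) -> None:
    """Write scores as CAFA-style (protein_id, term_id, score) TSV rows."""
    with open(path, "w") as fh:
        for i, pid in enumerate(proteins):
            for j, term in enumerate(terms):
                fh.write(f"{pid}\t{term}\t{preds[i, j]:.6f}\n")


class GraphCbamGoClassifier(BaseEstimator):
    """Multilabel GO classifier over residue contact graphs.

    scikit-learn-style estimator. ``X`` is a list of
    :class:`ProteinRecord`; ``y`` is the aligned binary P×L label matrix.
    Fitted attributes: ``state_`` (trained parameters), ``history_``
    (loss/validation trace), ``n_labels_``.

    Parameters expose the architecture (hidden width, convolution depth,
    channel reduction, pooling ratio, ablation flags) and the optimizer
    (epochs, batch size, learning rate, early-stop patience). A validation
    set may be passed to ``fit`` for best-epoch selection on Fmax.
    """

    def __init__(
        self,
        hidden_dim: int = 128,
        n_conv_layers: int = 2,
        channel_reduction: int = 2,
        spatial_hidden: int = 8,
        pool_ratio: float = 0.5,
        classifier_hidden: int = 512,
        in_dim: int = 56,
        embed_dim: int = 30,
        seq_dim: int = 1024,
        use_structure: bool = True,
        use_onehot: bool = True,
        use_cbam: bool = True,
        score_gated_pool: bool = True,
        classifier_dropout: float = 0.3,
        seq_dropout: float = 0.3,
        epochs: int = 120,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        early_stop_patience: int = 30,
        ema_decay: float = 0.98,
        seed: int = 0,
    ):
        self.hidden_dim = hidden_dim
        self.n_conv_layers = n_conv_layers
        self.channel_reduction = channel_reduction
        self.spatial_hidden = spatial_hidden
        self.pool_ratio = pool_ratio
        self.classifier_hidden = classifier_hidden
        self.in_dim = in_dim
        self.embed_dim = embed_dim
        self.seq_dim = seq_dim
        self.use_structure = use_structure
        self.use_onehot = use_onehot
        self.use_cbam = use_cbam
        self.score_gated_pool = score_gated_pool
        self.classifier_dropout = classifier_dropout
        self.seq_dropout = seq_dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.early_stop_patience = early_stop_patience
        self.ema_decay = ema_decay
        self.seed = seed

    def _model_config(self, n_labels: int) -> M.ModelConfig:
        return M.ModelConfig(
            n_labels=n_labels,
            in_dim=self.in_dim,
            embed_dim=self.embed_dim,
            hidden_dim=self.hidden_dim,
            n_conv_layers=self.n_conv_layers,
            channel_reduction=self.channel_reduction,
            spatial_hidden=self.spatial_hidden,
            pool_ratio=self.pool_ratio,
            seq_dim=self.seq_dim,
            classifier_hidden=self.classifier_hidden,
            use_structure=self.use_structure,
            use_onehot=self.use_onehot,
            use_cbam=self.use_cbam,
            score_gated_pool=self.score_gated_pool,
            classifier_dropout=self.classifier_dropout,
            seq_dropout=self.seq_dropout,
            seed=self.seed,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            early_stop_patience=self.early_stop_patience,
            ema_decay=self.ema_decay,
            seed=self.seed,
        )

    def fit(
        self,
        X: list[ProteinRecord],
        y: np.ndarray,
        X_val: list[ProteinRecord] | None = None,
        y_val: np.ndarray | None = None,
    ) -> "GraphCbamGoClassifier":
        y = np.asarray(y)
        if y.ndim != 2 or len(X) != y.shape[0]:
            raise ValueError("y must be a binary P×L matrix aligned with X")
        self.n_labels_ = y.shape[1]
        state = M.init_model_state(self._model_config(self.n_labels_))
        self.state_, self.history_ = train(
            state, X, y, self._train_config(),
            val_dataset=X_val, val_labels=y_val,
        )
        return self

    def predict_proba(self, X: list[ProteinRecord]) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "state_")
        return predict(self.state_, X)

    def predict(self, X: list[ProteinRecord], threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(np.int8)

    def score(self, X: list[ProteinRecord], y: np.ndarray) -> float:
        """Protein-centric Fmax on (X, y)."""
        value, _ = fmax(self.predict_proba(X), np.asarray(y))
        return value
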