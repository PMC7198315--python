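"""Classifiers: linear baselines on paragraph-vector features and the CNN.

Three model families are supported, each in a "not tagged" (whole
document) and a "tagged" (positive/negative sub-document) version:

* logistic regression and linear SVM, one-vs-rest over the 11
  categories, on 400-/800-dimensional paragraph-vector features;
* the dual-branch CNN, which consumes token-id sequences directly
  (input width 1500 by default) with its embedding layer initialized
  from the trained DBOW word vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from ._network import DualBranchCNN, _sigmoid
from .data_model import Category, N_CATEGORIES
from .embeddings import EmbeddingModel

__all__ = [
    "PAD_ID",
    "UNK_ID",
    "Vocabulary",
    "build_vocabulary",
    "encode_tokens",
    "embedding_matrix",
    "CnnConfig",
    "build_cnn",
    "train_cnn",
    "predict",
    "train_linear",
    "LinearModel",
    "PredictionSet",
    "labels_to_matrix",
]

logger = logging.getLogger(__name__)

PAD_ID = 0
UNK_ID = 1
_N_RESERVED = 2
_EMBED_INIT_STD = 0.05


@dataclass
class Vocabulary:
    """Token -> id mapping with reserved PAD (0) and UNK (1) rows."""

    token_to_id: dict[str, int]

    def __len__(self) -> int:
        return len(self.token_to_id) + _N_RESERVED

    def get(self, token: str) -> int:
        return self.token_to_id.get(token, UNK_ID)


def build_vocabulary(token_docs: list[list[str]], min_count: int = 1) -> Vocabulary:
    """Vocabulary from the training partition only (no test leakage)."""
    counts: dict[str, int] = {}
    for doc in token_docs:
        for tok in doc:
            counts[tok] = counts.get(tok, 0) + 1
    tokens = sorted(t for t, c in counts.items() if c >= min_count)
    return Vocabulary({t: i + _N_RESERVED for i, t in enumerate(tokens)})


def encode_tokens(tokens: list[str], vocab: Vocabulary, max_len: int = 1500) -> np.ndarray:
    """Head-truncate/right-pad a token list to a fixed-length id sequence."""
    ids = np.full(max_len, PAD_ID, dtype=np.int64)
    for i, tok in enumerate(tokens[:max_len]):
        ids[i] = vocab.get(tok)
    return ids


def embedding_matrix(dbow: EmbeddingModel, vocab: Vocabulary) -> np.ndarray:
    """Embedding-layer initializer from trained DBOW word vectors.

    Rows follow the classifier vocabulary; PAD and UNK rows (and any
    token unseen by the embedding model) are zero.
    """
    mat = np.zeros((len(vocab), dbow.vector_size))
    filled = np.zeros(len(vocab), dtype=bool)
    for tok, i in vocab.token_to_id.items():
        j = dbow.vocabulary.get(tok)
        if j is not None:
            mat[i] = dbow.word_vectors[j]
            filled[i] = True
    # rescale to a standard embedding-init magnitude; word-vector norms from
    # a small training corpus are otherwise tiny and starve the conv stack
    scale = mat[filled].std()
    if scale > 0:
        mat *= _EMBED_INIT_STD / scale
    return mat


@dataclass
class CnnConfig:
    n_conv_layers: int = 3
    channels: int = 128
    kernel_width: int = 5
    dropout_rate: float = 0.5
    dense_width: int = 128
    n_outputs: int = N_CATEGORIES
    output_activation: str = "sigmoid"  # "softmax" for the fidelity mode
    max_len: int = 1500
    embed_dim: int = 200
    epochs: int = 50
    early_stopping_patience: int = 5
    batch_size: int = 32
    learning_rate: float = 1e-3
    threshold: float | None = None  # default depends on activation
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_conv_layers", "channels", "kernel_width", "dense_width",
                     "n_outputs", "max_len", "embed_dim", "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_outputs != N_CATEGORIES:
            raise ValueError(f"n_outputs must be {N_CATEGORIES}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.output_activation not in ("sigmoid", "softmax"):
            raise ValueError(f"unknown output activation {self.output_activation!r}")
        if self.threshold is not None and not 0 < self.threshold < 1:
            raise ValueError("decision threshold must lie in (0, 1)")

    @property
    def decision_threshold(self) -> float:
        if self.threshold is not None:
            return self.threshold
        return 0.5 if self.output_activation == "sigmoid" else 1.0 / self.n_outputs


def build_cnn(config: CnnConfig, embedding_init: np.ndarray, mode: str) -> DualBranchCNN:
    """Instantiate the (dual-branch) CNN with the given embedding init."""
    if embedding_init.ndim != 2 or embedding_init.shape[1] != config.embed_dim:
        raise ValueError(
            f"embedding_init must have row dimension {config.embed_dim}, "
            f"got {embedding_init.shape}"
        )
    model = DualBranchCNN(
        embedding_init,
        mode=mode,
        n_conv_layers=config.n_conv_layers,
        channels=config.channels,
        kernel_width=config.kernel_width,
        dropout_rate=config.dropout_rate,
        dense_width=config.dense_width,
        n_outputs=config.n_outputs,
        output_activation=config.output_activation,
        seed=config.seed,
    )
    model.config = config
    return model


def labels_to_matrix(label_sets: list[frozenset[Category]]) -> np.ndarray:
    y = np.zeros((len(label_sets), N_CATEGORIES))
    for i, labels in enumerate(label_sets):
        for c in labels:
            y[i, int(c)] = 1.0
    return y


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _eval_loss(model: DualBranchCNN, inputs, targets, batch_size: int) -> float:
    n = targets.shape[0]
    total = 0.0
    for start in range(0, n, batch_size):
        sl = slice(start, start + batch_size)
        probs, _ = model.forward(tuple(x[sl] for x in inputs), train=False)
        t = targets[sl]
        if model.output_activation == "softmax":
            tn = t / np.maximum(t.sum(axis=1, keepdims=True), 1e-12)
            total += -np.sum(tn * np.log(probs + 1e-12))
        else:
            total += -np.sum(
                t * np.log(probs + 1e-12) + (1 - t) * np.log(1 - probs + 1e-12)
            ) / probs.shape[1]
    return total / n


def train_cnn(
    model: DualBranchCNN,
    train_inputs: tuple[np.ndarray, ...],
    train_targets: np.ndarray,
    val_inputs: tuple[np.ndarray, ...] | None = None,
    val_targets: np.ndarray | None = None,
    config: CnnConfig | None = None,
) -> list[dict]:
    """Mini-batch Adam training with early stopping on validation loss.

    Runs at most ``config.epochs`` epochs and stops after
    ``early_stopping_patience`` consecutive epochs without improvement,
    restoring the best-epoch weights.  Returns the per-epoch log.
    """
    config = config or model.config
    n = train_targets.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed + 1)
    opt = model.make_optimizer(config.learning_rate)
    log: list[dict] = []
    best_loss, best_state, bad_epochs = np.inf, None, 0
    for epoch in range(config.epochs):
        epoch_loss, n_batches = 0.0, 0
        for idx in _batches(n, config.batch_size, rng):
            loss, grads = model.loss_and_grads(
                tuple(x[idx] for x in train_inputs), train_targets[idx]
            )
            opt.step(model.params, grads)
            epoch_loss += loss
            n_batches += 1
        entry = {"epoch": epoch, "train_loss": epoch_loss / max(1, n_batches)}
        if val_targets is not None and len(val_targets):
            val_loss = _eval_loss(model, val_inputs, val_targets, config.batch_size)
            entry["val_loss"] = val_loss
            if val_loss < best_loss - 1e-12:
                best_loss, best_state, bad_epochs = val_loss, model.state_copy(), 0
            else:
                bad_epochs += 1
            log.append(entry)
            if bad_epochs >= config.early_stopping_patience:
                break
        else:
            log.append(entry)
    if best_state is not None:
        model.load_state(best_state)
    _refresh_batchnorm_stats(model, train_inputs, config.batch_size)
    model.training_log = log
    return log


def _refresh_batchnorm_stats(model, inputs, batch_size: int, n_passes: int = 3) -> None:
    # re-estimate batch-norm running statistics under the final weights
    n = inputs[0].shape[0]
    for _ in range(n_passes):
        for start in range(0, n, batch_size):
            model.forward(tuple(x[start : start + batch_size] for x in inputs), train=True)


@dataclass
class PredictionSet:
    """Per-sample category scores plus thresholded label sets."""

    scores: np.ndarray  # (n, 11), each value in [0, 1]
    threshold: float
    label_sets: list[frozenset[Category]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.label_sets:
            self.label_sets = [
                _threshold_row(row, self.threshold) for row in self.scores
            ]


def _threshold_row(row: np.ndarray, tau: float) -> frozenset[Category]:
    chosen = np.flatnonzero(row >= tau)
    if chosen.size == 0:
        chosen = np.array([int(row.argmax())])  # non-empty backstop
    return frozenset(Category(int(i)) for i in chosen)


def predict(
    model: DualBranchCNN,
    inputs: tuple[np.ndarray, ...],
    threshold: float | None = None,
    batch_size: int = 64,
) -> PredictionSet:
    config = getattr(model, "config", None)
    if threshold is None:
        threshold = config.decision_threshold if config else 0.5
    if not 0 < threshold < 1:
        raise ValueError("decision threshold must lie in (0, 1)")
    n = inputs[0].shape[0]
    chunks = []
    for start in range(0, n, batch_size):
        probs, _ = model.forward(tuple(x[start : start + batch_size] for x in inputs),
                                 train=False)
        chunks.append(probs)
    scores = np.vstack(chunks) if chunks else np.zeros((0, model.n_outputs))
    return PredictionSet(scores=scores, threshold=threshold)


# ---------------------------------------------------------------------------
# linear baselines


@dataclass
class LinearModel:
    family: str  # "logistic" | "svm"
    estimators: dict[int, object]
    constant_scores: dict[int, float]
    threshold: float = 0.5

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        scores = np.zeros((X.shape[0], N_CATEGORIES))
        for c in range(N_CATEGORIES):
            if c in self.estimators:
                est = self.estimators[c]
                if self.family == "logistic":
                    scores[:, c] = est.predict_proba(X)[:, 1]
                else:
                    # squash the SVM margin into [0, 1]
                    scores[:, c] = _sigmoid(est.decision_function(X))
            else:
                scores[:, c] = self.constant_scores.get(c, 0.0)
        return scores

    def predict(self, X: np.ndarray) -> PredictionSet:
        return PredictionSet(scores=self.predict_scores(X), threshold=self.threshold)


def train_linear(
    features: np.ndarray,
    label_sets: list[frozenset[Category]],
    family: str = "logistic",
    seed: int = 0,
) -> LinearModel:
    """One-vs-rest linear classifier per category with [0, 1] scores.

    Categories without both a positive and a negative training example
    are skipped with a warning and score their observed constant.
    """
    if family not in ("logistic", "svm"):
        raise ValueError(f"unknown family {family!r}")
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != len(label_sets):
        raise ValueError("features and labels must align (n_samples rows)")
    Y = labels_to_matrix(label_sets)
    estimators: dict[int, object] = {}
    constants: dict[int, float] = {}
    for c in range(N_CATEGORIES):
        y = Y[:, c]
        if y.min() == y.max():
            logger.warning(
                "category %s has a single class in training; skipped",
                Category(c).label,
            )
            constants[c] = float(y.max())
            continue
        if family == "logistic":
            est = LogisticRegression(max_iter=2000, random_state=seed)
        else:
            est = LinearSVC(random_state=seed)
        est.fit(X, y)
        estimators[c] = est
    return LinearModel(family=family, estimators=estimators, constant_scores=constants)
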