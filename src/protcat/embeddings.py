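"""Paragraph-vector document embeddings (DBOW and DMC variants).

Documents and words share a continuous space trained with negative
sampling:

* DBOW (distributed bag of words): the document vector alone predicts
  each of its words; the output word matrix doubles as the word
  representation used to initialize the classifier's embedding layer.
* DMC (distributed memory, concatenated): the document vector is
  concatenated with the input vectors of the window words around a
  centre word to predict that centre word.

Default hyperparameters: vector size 200, window 10, 100 epochs.  A
publication is represented by the 400-dimensional concatenation
DBOW‖DMC; with evidence tagging the positive and negative sub-documents
are embedded separately, giving 800 dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocessing import preprocess_document
from .tagging import TaggedPair

__all__ = [
    "EmbeddingModel",
    "FeatureVector",
    "train_embedding",
    "infer_doc_vector",
    "featurize",
    "document_tokens",
]

_NOISE_EXPONENT = 0.75
_MIN_ALPHA = 1e-4


@dataclass
class EmbeddingModel:
    variant: str  # "DBOW" | "DMC"
    vector_size: int
    window: int
    epochs: int
    negative: int
    alpha: float
    min_count: int
    seed: int
    vocabulary: dict[str, int] = field(default_factory=dict)
    word_vectors: np.ndarray | None = None  # (V, size) input/word representations
    _output: np.ndarray | None = None  # output weights for negative sampling
    doc_vectors: np.ndarray | None = None  # (n_train_docs, size)
    _noise_cdf: np.ndarray | None = None

    def save(self, path: str | Path) -> None:
        tokens = sorted(self.vocabulary, key=self.vocabulary.get)
        np.savez_compressed(
            path,
            meta=np.array(
                [self.vector_size, self.window, self.epochs, self.negative,
                 self.min_count, self.seed], dtype=np.int64,
            ),
            alpha=np.array([self.alpha]),
            variant=np.array([self.variant]),
            tokens=np.array(tokens),
            word_vectors=self.word_vectors,
            output=self._output,
            doc_vectors=self.doc_vectors,
            noise_cdf=self._noise_cdf,
        )

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingModel":
        data = np.load(path, allow_pickle=False)
        meta = data["meta"]
        model = cls(
            variant=str(data["variant"][0]),
            vector_size=int(meta[0]),
            window=int(meta[1]),
            epochs=int(meta[2]),
            negative=int(meta[3]),
            min_count=int(meta[4]),
            seed=int(meta[5]),
            alpha=float(data["alpha"][0]),
        )
        model.vocabulary = {tok: i for i, tok in enumerate(data["tokens"])}
        model.word_vectors = data["word_vectors"]
        model._output = data["output"]
        model.doc_vectors = data["doc_vectors"]
        model._noise_cdf = data["noise_cdf"]
        return model


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _build_vocab(token_docs, min_count):
    counts: dict[str, int] = {}
    for doc in token_docs:
        for tok in doc:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = {t: i for i, t in enumerate(sorted(t for t, c in counts.items() if c >= min_count))}
    freqs = np.array([counts[t] for t in sorted(vocab, key=vocab.get)], dtype=np.float64)
    return vocab, freqs


def _noise_cdf(freqs: np.ndarray) -> np.ndarray:
    p = freqs ** _NOISE_EXPONENT
    return np.cumsum(p / p.sum())


def _sample_negatives(rng, cdf, n):
    return np.searchsorted(cdf, rng.random(n))


def train_embedding(
    token_docs: list[list[str]],
    variant: str = "DBOW",
    vector_size: int = 200,
    window: int = 10,
    epochs: int = 100,
    negative: int = 5,
    alpha: float = 0.025,
    min_count: int = 2,
    seed: int = 0,
) -> EmbeddingModel:
    """Train a paragraph-vector model on pre-normalized token documents.

    Deterministic for a fixed seed (single-worker SGD, fixed update
    order with per-epoch seeded shuffling of documents).
    """
    if variant not in ("DBOW", "DMC"):
        raise ValueError(f"unknown variant {variant!r}")
    if len(token_docs) < 2:
        raise ValueError("need at least 2 documents to train an embedding")
    vocab, freqs = _build_vocab(token_docs, min_count)
    if not vocab:
        raise ValueError("empty vocabulary after min-count filtering")

    rng = np.random.default_rng(seed)
    size, n_docs, n_vocab = vector_size, len(token_docs), len(vocab)
    docs_ids = [np.array([vocab[t] for t in doc if t in vocab], dtype=np.int64)
                for doc in token_docs]
    cdf = _noise_cdf(freqs)

    doc_vecs = (rng.random((n_docs, size)) - 0.5) / size
    if variant == "DBOW":
        word_in = (rng.random((n_vocab, size)) - 0.5) / size
        out_dim = size
    else:
        word_in = (rng.random((n_vocab, size)) - 0.5) / size
        out_dim = size * (2 * window + 1)
    output = np.zeros((n_vocab, out_dim))

    total_steps = max(1, epochs * sum(len(d) for d in docs_ids))
    step = 0
    for epoch in range(epochs):
        order = rng.permutation(n_docs)
        for d in order:
            ids = docs_ids[d]
            if ids.size == 0:
                continue
            for pos, w in enumerate(ids):
                lr = max(_MIN_ALPHA, alpha * (1 - step / total_steps))
                step += 1
                negs = _sample_negatives(rng, cdf, negative)
                targets = np.concatenate(([w], negs))
                labels = np.zeros(len(targets))
                labels[0] = 1.0
                if variant == "DBOW":
                    h = doc_vecs[d]
                else:
                    ctx = _context_ids(ids, pos, window)
                    h = np.concatenate(
                        [doc_vecs[d]]
                        + [word_in[c] if c >= 0 else _ZERO(size) for c in ctx]
                    )
                f = _sigmoid(output[targets] @ h)
                g = (labels - f) * lr
                grad_h = g @ output[targets]
                output[targets] += np.outer(g, h)
                if variant == "DBOW":
                    doc_vecs[d] += grad_h
                else:
                    doc_vecs[d] += grad_h[:size]
                    for j, c in enumerate(ctx):
                        if c >= 0:
                            word_in[c] += grad_h[(j + 1) * size : (j + 2) * size]

    model = EmbeddingModel(
        variant=variant, vector_size=size, window=window, epochs=epochs,
        negative=negative, alpha=alpha, min_count=min_count, seed=seed,
        vocabulary=vocab,
    )
    # for DBOW the trained output matrix is the word representation
    model.word_vectors = output.copy() if variant == "DBOW" else word_in
    model._output = output
    model.doc_vectors = doc_vecs
    model._noise_cdf = cdf
    if not (np.isfinite(model.word_vectors).all() and np.isfinite(doc_vecs).all()):
        raise FloatingPointError("non-finite values in trained embedding")
    return model


def _context_ids(ids: np.ndarray, pos: int, window: int) -> list[int]:
    """Window token ids around ``pos`` (excluded), -1 padding outside."""
    out = []
    for off in range(-window, window + 1):
        if off == 0:
            continue
        j = pos + off
        out.append(int(ids[j]) if 0 <= j < len(ids) else -1)
    return out


def _ZERO(size):
    return np.zeros(size)


def infer_doc_vector(model: EmbeddingModel, tokens: list[str], epochs: int | None = None,
                     seed: int = 0) -> np.ndarray:
    """Embed an unseen token document with frozen word/output weights.

    Empty or fully out-of-vocabulary documents map to the zero vector.
    """
    ids = np.array([model.vocabulary[t] for t in tokens if t in model.vocabulary],
                   dtype=np.int64)
    size = model.vector_size
    if ids.size == 0:
        return np.zeros(size)
    rng = np.random.default_rng(seed)
    vec = (rng.random(size) - 0.5) / size
    output, cdf = model._output, model._noise_cdf
    n_epochs = model.epochs if epochs is None else epochs
    total_steps = max(1, n_epochs * ids.size)
    step = 0
    for _ in range(n_epochs):
        for pos, w in enumerate(ids):
            lr = max(_MIN_ALPHA, model.alpha * (1 - step / total_steps))
            step += 1
            negs = _sample_negatives(rng, cdf, model.negative)
            targets = np.concatenate(([w], negs))
            labels = np.zeros(len(targets))
            labels[0] = 1.0
            if model.variant == "DBOW":
                h = vec
            else:
                ctx = _context_ids(ids, pos, model.window)
                h = np.concatenate(
                    [vec] + [model.word_vectors[c] if c >= 0 else np.zeros(size) for c in ctx]
                )
            f = _sigmoid(output[targets] @ h)
            g = (labels - f) * lr
            grad_h = g @ output[targets]
            vec += grad_h[:size]
    return vec


@dataclass
class FeatureVector:
    """Fixed-length paragraph-vector features for one classification sample.

    400 dimensions in ``not_tagged`` mode (DBOW‖DMC of the whole
    document), 800 in ``tagged`` mode (400 for the positive sub-document
    followed by 400 for the negative one).
    """

    values: np.ndarray
    provenance: str  # "not_tagged" | "tagged"


def document_tokens(doc, stopwords=None) -> list[str]:
    """Full normalized token stream of a Document."""
    return [t for ts in preprocess_document(doc, stopwords) for t in ts.tokens]


def _embed_both(dbow: EmbeddingModel, dmc: EmbeddingModel, tokens, seed):
    return np.concatenate(
        [infer_doc_vector(dbow, tokens, seed=seed), infer_doc_vector(dmc, tokens, seed=seed)]
    )


def featurize(item, dbow: EmbeddingModel, dmc: EmbeddingModel, mode: str,
              stopwords=None, seed: int = 0) -> FeatureVector:
    """Build the classification feature vector for a document or tagged pair."""
    if dbow.vector_size != dmc.vector_size:
        raise ValueError("DBOW and DMC models must share vector_size")
    if mode == "not_tagged":
        tokens = item if isinstance(item, list) else document_tokens(item, stopwords)
        values = _embed_both(dbow, dmc, tokens, seed)
    elif mode == "tagged":
        if not isinstance(item, TaggedPair):
            raise TypeError("tagged mode requires a TaggedPair")
        values = np.concatenate(
            [_embed_both(dbow, dmc, item.positive_doc, seed),
             _embed_both(dbow, dmc, item.negative_doc, seed)]
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return FeatureVector(values=values, provenance=mode)
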