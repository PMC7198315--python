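"""End-to-end experiment: synthetic corpus -> tagging -> CNN comparison.

Runs the full method on a generated corpus and measures whether the
accession-specific tagged representation beats the whole-document one —
the central claim the dual-branch design rests on.  Problem sizes here
are the package's scaled study defaults (a few hundred examples, short
documents, CNN input width 64) chosen so a single comparison completes
in about a minute on one CPU; every stage accepts the full-size
parameters as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import group_split
from .embeddings import train_embedding
from .evaluation import multilabel_metrics, per_sample_f1, tagging_eval
from .models import (
    CnnConfig,
    build_cnn,
    build_vocabulary,
    embedding_matrix,
    encode_tokens,
    predict,
    train_cnn,
)
from .synthetic import GeneratorConfig, generate_corpus, oracle_labels
from .tagging import tag_corpus

__all__ = ["ExperimentConfig", "run_comparison", "AMBIGUITY_CORPUS"]

# Study conditions for the ambiguity corpus: multiple accessions per
# document with independently drawn category sets, so the whole-document
# model faces identical inputs with conflicting labels.
AMBIGUITY_CORPUS = GeneratorConfig(
    n_documents=200,
    accessions_per_doc=(2, 3),
    sentences_per_doc=(4, 6),
    tokens_per_sentence=(4, 7),
    vocab_size=150,
    n_signal_tokens_per_category=3,
    signal_strength=0.9,
    noise_rate=0.2,
    label_prior=0.2,
    seed=13,
)


@dataclass
class ExperimentConfig:
    corpus: GeneratorConfig = field(default_factory=lambda: AMBIGUITY_CORPUS)
    k: int = 0
    embedding_epochs: int = 20
    embedding_window: int = 3
    cnn: CnnConfig = None  # defaults to the scaled config below

    def __post_init__(self) -> None:
        if self.cnn is None:
            self.cnn = CnnConfig(
                max_len=48, epochs=60, early_stopping_patience=8,
                batch_size=16, learning_rate=5e-4,
            )


def _doc_token_map(corpus) -> dict[str, list[str]]:
    from .embeddings import document_tokens

    return {doc.doc_id: document_tokens(doc) for doc in corpus.documents}


def run_comparison(seed: int, config: ExperimentConfig | None = None) -> dict:
    """Train tagged and not-tagged CNNs on one generated corpus.

    Returns the test-set metric report of both models plus the
    sentence-level tagging scores against the generator's ground truth.
    """
    cfg = config or ExperimentConfig()
    corpus_cfg = replace(cfg.corpus, seed=int(np.random.default_rng(seed).integers(2**31)))
    corpus = generate_corpus(corpus_cfg)
    annotations, gold_positive = oracle_labels(corpus)

    split = group_split(annotations, seed=seed)
    pairs = tag_corpus(corpus.documents, corpus.features, annotations, k=cfg.k)

    part = [split.partition(ann.doc_id) for ann in annotations]
    idx = {p: [i for i, q in enumerate(part) if q == p] for p in ("train", "validation", "test")}

    # tagger quality against generating truth (whole corpus)
    tag_scores = tagging_eval(
        gold_positive, [set(p.positive_indices) for p in pairs]
    )

    full_tokens = _doc_token_map(corpus)
    train_docs = [full_tokens[annotations[i].doc_id] for i in idx["train"]]
    dbow = train_embedding(
        train_docs, variant="DBOW", vector_size=cfg.cnn.embed_dim,
        window=cfg.embedding_window, epochs=cfg.embedding_epochs, seed=seed,
    )
    vocab = build_vocabulary(train_docs)
    emb = embedding_matrix(dbow, vocab)

    max_len = cfg.cnn.max_len
    X_pos = np.stack([encode_tokens(p.positive_doc, vocab, max_len) for p in pairs])
    X_neg = np.stack([encode_tokens(p.negative_doc, vocab, max_len) for p in pairs])
    X_full = np.stack(
        [encode_tokens(full_tokens[ann.doc_id], vocab, max_len) for ann in annotations]
    )
    from .models import labels_to_matrix

    Y = labels_to_matrix([ann.categories for ann in annotations])
    gold_sets = [ann.categories for ann in annotations]

    results: dict = {
        "seed": seed,
        "n_examples": len(annotations),
        "n_train": len(idx["train"]),
        "n_test": len(idx["test"]),
        "tagging": tag_scores,
    }
    for mode in ("tagged", "not_tagged"):
        cnn_cfg = replace(cfg.cnn, seed=seed)
        model = build_cnn(cnn_cfg, emb, mode)
        if mode == "tagged":
            inputs = (X_pos, X_neg)
        else:
            inputs = (X_full,)
        tr, va, te = idx["train"], idx["validation"], idx["test"]
        train_cnn(
            model,
            tuple(x[tr] for x in inputs), Y[tr],
            tuple(x[va] for x in inputs), Y[va],
            cnn_cfg,
        )
        preds = predict(model, tuple(x[te] for x in inputs))
        report = multilabel_metrics([gold_sets[i] for i in te], preds.label_sets)
        results[mode] = {
            "micro_f1": report.micro_f1,
            "macro_f1": report.macro_f1,
            "micro_precision": report.micro_precision,
            "micro_recall": report.micro_recall,
            "per_sample_f1": per_sample_f1([gold_sets[i] for i in te], preds.label_sets),
            "report": report,
        }
    results["tagged_beats_not_tagged_macro"] = (
        results["tagged"]["macro_f1"] > results["not_tagged"]["macro_f1"]
    )
    return results
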