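"""Synthetic corpus generator with the statistical structure the method assumes.

Each generated document carries several protein accessions; every
accession has its own category set and its own evidence sentences, which
(i) mention one of the accession's generated name strings verbatim and
(ii) carry category-specific signal tokens with a configurable
probability.  Background sentences of shared vocabulary are interleaved.
This reproduces the central ambiguity of knowledge-base curation — one
publication, different label sets per protein — in a fully controlled,
seeded form, so the evidence tagger and the tagged-vs-not-tagged
classifier comparison can be validated without any external data.

Category signal is carried by dedicated pseudo-tokens (random alphabetic
strings that are Porter-stemming fixed points), not real biomedical
vocabulary, so learnability is controlled by ``signal_strength`` alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._porter import porter_stem
from .data_model import (
    AnnotationExample,
    Category,
    Document,
    N_CATEGORIES,
    ProteinFeatureSet,
)
from .preprocessing import load_stopwords

__all__ = ["GeneratorConfig", "SyntheticCorpus", "generate_corpus", "oracle_labels"]

_LETTERS = "abcdefghijklmnopqrstuvwxyz"
_UPPER = "BCDFGHJKLMNPQRSTVWXZ"


@dataclass
class GeneratorConfig:
    n_documents: int = 100
    accessions_per_doc: tuple[int, int] = (1, 4)  # uniform inclusive range
    sentences_per_doc: tuple[int, int] = (4, 8)
    tokens_per_sentence: tuple[int, int] = (5, 9)
    vocab_size: int = 150  # total words; signal tokens are carved out of it
    n_signal_tokens_per_category: int = 3
    signal_strength: float = 0.9  # P(evidence sentence carries a gold-category signal token)
    noise_rate: float = 0.3  # P(a non-reserved sentence is pure background)
    label_prior: float = 0.2  # per-category inclusion probability
    untaggable_fraction: float = 0.0  # P(an annotation's names are omitted from the text)
    seed: int = 13

    def __post_init__(self) -> None:
        for p in (self.signal_strength, self.noise_rate, self.label_prior,
                  self.untaggable_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_documents < 0:
            raise ValueError("n_documents must be non-negative")
        for name in ("vocab_size", "n_signal_tokens_per_category"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SyntheticCorpus:
    documents: list[Document]
    features: dict[str, ProteinFeatureSet]
    annotations: list[AnnotationExample]
    evidence: dict[tuple[str, str], list[int]]  # (doc_id, accession) -> gold indices
    untaggable: set[tuple[str, str]]
    # annotations of the duplicated ambiguity document: labels are redrawn
    # there, deliberately decoupled from the signal tokens in the text
    relabeled: set[tuple[str, str]]
    signal_tokens: dict[Category, list[str]]
    config: GeneratorConfig


def _random_word(rng: np.random.Generator, taken: set[str]) -> str:
    """A 4-7 letter word that is its own Porter stem and not a stopword."""
    stop = load_stopwords()
    for _ in range(10_000):
        n = int(rng.integers(4, 8))
        word = "".join(_LETTERS[i] for i in rng.integers(0, 26, n))
        if word in taken or word in stop or porter_stem(word) != word:
            continue
        return word
    raise RuntimeError("could not generate a fresh vocabulary word")


def _draw_categories(rng: np.random.Generator, prior: float) -> frozenset[Category]:
    mask = rng.random(N_CATEGORIES) < prior
    if not mask.any():
        mask[int(rng.integers(N_CATEGORIES))] = True
    return frozenset(Category(int(i)) for i in np.flatnonzero(mask))


def generate_corpus(config: GeneratorConfig) -> SyntheticCorpus:
    """Generate a fully seeded corpus (documents, features, annotations, truth).

    When ``n_documents >= 10`` the last document is a verbatim text copy
    of the first with independently redrawn category sets for the same
    accessions — the canonical ambiguity case of identical input text
    with accession-dependent labels.
    """
    cfg = config
    n_signal_total = N_CATEGORIES * cfg.n_signal_tokens_per_category
    n_background = cfg.vocab_size - n_signal_total
    if n_background < 1:
        raise ValueError(
            f"vocab_size={cfg.vocab_size} too small for "
            f"{n_signal_total} signal tokens plus background vocabulary"
        )
    rng = np.random.default_rng(cfg.seed)

    taken: set[str] = set()
    words = []
    for _ in range(cfg.vocab_size):
        w = _random_word(rng, taken)
        taken.add(w)
        words.append(w)
    signal_tokens = {
        Category(c): words[c * cfg.n_signal_tokens_per_category
                           : (c + 1) * cfg.n_signal_tokens_per_category]
        for c in range(N_CATEGORIES)
    }
    background = words[n_signal_total:]

    documents: list[Document] = []
    features: dict[str, ProteinFeatureSet] = {}
    annotations: list[AnnotationExample] = []
    evidence: dict[tuple[str, str], list[int]] = {}
    untaggable: set[tuple[str, str]] = set()
    relabeled: set[tuple[str, str]] = set()
    acc_counter = 0

    def new_feature_set() -> ProteinFeatureSet:
        nonlocal acc_counter
        acc_counter += 1
        prefix = "".join(_UPPER[i] for i in rng.integers(0, len(_UPPER), 3))
        fs = ProteinFeatureSet(
            accession=f"SYN{acc_counter:04d}",
            entry_name=f"{prefix}{acc_counter}_SYN",
            names=[f"{prefix.capitalize()}in-{acc_counter}"],
            genes=[f"{prefix}{acc_counter}"],
        )
        features[fs.accession] = fs
        return fs

    def background_sentence() -> str:
        n = int(rng.integers(cfg.tokens_per_sentence[0], cfg.tokens_per_sentence[1] + 1))
        toks = [background[int(i)] for i in rng.integers(0, len(background), n)]
        return _sentence(toks)

    def evidence_sentence(fs: ProteinFeatureSet, cats: frozenset[Category],
                          hide_name: bool) -> str:
        toks: list[str] = []
        if not hide_name:
            choices = fs.searchable_strings
            toks.append(choices[int(rng.integers(len(choices)))])
        for c in sorted(cats):
            if rng.random() < cfg.signal_strength:
                pool = signal_tokens[c]
                toks.append(pool[int(rng.integers(len(pool)))])
        n_extra = int(rng.integers(2, 5))
        toks.extend(background[int(i)] for i in rng.integers(0, len(background), n_extra))
        perm = rng.permutation(len(toks))
        return _sentence([toks[int(i)] for i in perm])

    duplicate_last = cfg.n_documents >= 10
    n_generate = cfg.n_documents - 1 if duplicate_last else cfg.n_documents

    for d in range(n_generate):
        doc_id = f"d{d:05d}"
        n_acc = int(rng.integers(cfg.accessions_per_doc[0], cfg.accessions_per_doc[1] + 1))
        n_sent = max(
            int(rng.integers(cfg.sentences_per_doc[0], cfg.sentences_per_doc[1] + 1)),
            n_acc + 1,
        )
        accs = [new_feature_set() for _ in range(n_acc)]
        cats = {fs.accession: _draw_categories(rng, cfg.label_prior) for fs in accs}
        hidden = {
            fs.accession: bool(rng.random() < cfg.untaggable_fraction) for fs in accs
        }

        # every accession is guaranteed at least one evidence sentence
        owner = [-1] * n_sent  # -1: background
        reserved = rng.choice(n_sent, size=n_acc, replace=False)
        for a, s in enumerate(reserved):
            owner[int(s)] = a
        for s in range(n_sent):
            if owner[s] == -1 and rng.random() >= cfg.noise_rate:
                owner[s] = int(rng.integers(n_acc))

        sentences = []
        for s in range(n_sent):
            if owner[s] == -1:
                sentences.append(background_sentence())
            else:
                fs = accs[owner[s]]
                sentences.append(
                    evidence_sentence(fs, cats[fs.accession], hidden[fs.accession])
                )
        documents.append(Document(doc_id, " ".join(sentences)))
        for a, fs in enumerate(accs):
            annotations.append(
                AnnotationExample(doc_id, fs.accession, cats[fs.accession])
            )
            key = (doc_id, fs.accession)
            if hidden[fs.accession]:
                untaggable.add(key)
                evidence[key] = list(range(n_sent))
            else:
                evidence[key] = [s for s in range(n_sent) if owner[s] == a]

    if duplicate_last and documents:
        src = documents[0]
        dup_id = f"d{cfg.n_documents - 1:05d}"
        documents.append(Document(dup_id, src.text))
        src_annotations = [a for a in annotations if a.doc_id == src.doc_id]
        for ann in src_annotations:
            redrawn = _draw_categories(rng, cfg.label_prior)
            if redrawn == ann.categories:  # force a differing label set
                flip = Category(int(rng.integers(N_CATEGORIES)))
                redrawn = (
                    redrawn - {flip} if flip in redrawn and len(redrawn) > 1
                    else redrawn | {flip}
                )
            annotations.append(AnnotationExample(dup_id, ann.accession, redrawn))
            relabeled.add((dup_id, ann.accession))
            key = (src.doc_id, ann.accession)
            evidence[(dup_id, ann.accession)] = list(evidence[key])
            if key in untaggable:
                untaggable.add((dup_id, ann.accession))

    return SyntheticCorpus(
        documents=documents, features=features, annotations=annotations,
        evidence=evidence, untaggable=untaggable, relabeled=relabeled,
        signal_tokens=signal_tokens, config=cfg,
    )


def _sentence(tokens: list[str]) -> str:
    text = " ".join(tokens)
    return (text[0].upper() + text[1:] + ".") if text else "."


def oracle_labels(corpus: SyntheticCorpus):
    """Generating truth: (annotations, gold positive-sentence index sets).

    Aligned with ``corpus.annotations``; untaggable annotations expose
    all sentence indices (whole-document fallback convention).
    """
    gold_positive = [
        set(corpus.evidence[(ann.doc_id, ann.accession)]) for ann in corpus.annotations
    ]
    return corpus.annotations, gold_positive
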