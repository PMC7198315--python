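"""NLP normalization pipeline: sentence splitting, token normalization.

The pipeline prepares publication text for embedding and classification:
sentences are split with a rule-based boundary detector tuned for English
scientific prose, then each sentence is tokenized on non-alphanumeric
runs, lowercased, stopword-filtered, Porter-stemmed, purged of
single-character tokens, and finally every all-digit token is replaced by
the mask token ``_NUMBER_``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

from ._porter import porter_stem

__all__ = [
    "NUMBER_TOKEN",
    "TokenizedSentence",
    "load_stopwords",
    "split_sentences",
    "normalize_sentence",
    "preprocess_document",
]

NUMBER_TOKEN = "_NUMBER_"

# common abbreviations that a terminal period does not end a sentence after
_ABBREVIATIONS = frozenset(
    """al fig figs eq eqs ref refs vs etc ca approx resp
    dr mr mrs ms prof inc ltd st no
    i.e e.g cf spp subsp var""".split()
)

_BOUNDARY_RE = re.compile(r"([.!?]+)(\s+)(?=[\"'(\[]?[A-Z0-9])")
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")
_DIGITS_RE = re.compile(r"[0-9]+$")


@dataclass
class TokenizedSentence:
    """Normalized tokens of one raw sentence (may be empty)."""

    tokens: list[str] = field(default_factory=list)
    source_index: int = 0


@lru_cache(maxsize=None)
def _default_stopwords() -> frozenset[str]:
    text = resources.files("protcat.resources").joinpath("stopwords.txt").read_text()
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


def load_stopwords(path: str | Path | None = None) -> frozenset[str]:
    """Load a stopword list (one lowercase word per line); ships a default."""
    if path is None:
        return _default_stopwords()
    with open(path, encoding="utf-8") as fh:
        return frozenset(w.strip() for w in fh if w.strip())


def _is_boundary(text: str, match: re.Match) -> bool:
    head = text[: match.start()]
    word_m = re.search(r"([A-Za-z][A-Za-z.]*)$", head)
    if word_m:
        word = word_m.group(1).lower().rstrip(".")
        if word in _ABBREVIATIONS:
            return False
        if len(word) == 1 and word_m.group(1)[0].isupper():
            return False  # single initial, e.g. "J. Smith"
    return True


def split_sentences(text: str) -> list[str]:
    """Split raw text into ordered sentence strings.

    A boundary is a run of ``.!?`` followed by whitespace and an
    uppercase letter or digit, unless the preceding token is a known
    abbreviation or a single initial.  Joining the result with single
    spaces preserves every non-whitespace character of the input in
    order.
    """
    if not text or not text.strip():
        return []
    sentences: list[str] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        if not _is_boundary(text, m):
            continue
        sentences.append(text[start : m.end(1)].strip())
        start = m.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return [s for s in sentences if s]


def normalize_sentence(
    sentence: str, stopwords: frozenset[str] | None = None
) -> TokenizedSentence:
    """Normalize one raw sentence to its token list.

    Order of operations: tokenize on non-alphanumeric runs, lowercase,
    remove stopwords (matched on unstemmed forms), stem alphabetic
    tokens, drop tokens shorter than two characters, replace all-digit
    tokens by ``_NUMBER_``.
    """
    if stopwords is None:
        stopwords = _default_stopwords()
    tokens: list[str] = []
    for raw in _TOKEN_RE.findall(sentence):
        tok = raw.lower()
        if tok in stopwords:
            continue
        if tok.isalpha():
            tok = porter_stem(tok)
        if len(tok) < 2:
            continue
        if _DIGITS_RE.fullmatch(tok):
            tok = NUMBER_TOKEN
        tokens.append(tok)
    return TokenizedSentence(tokens=tokens)


def preprocess_document(doc, stopwords: frozenset[str] | None = None) -> list[TokenizedSentence]:
    """Split (if needed) and normalize a Document's sentences.

    Populates ``doc.sentences`` and returns one TokenizedSentence per raw
    sentence; sentences that normalize to nothing stay as empty token
    lists so sentence indices remain aligned for the evidence tagger.
    """
    if not doc.sentences:
        doc.sentences = split_sentences(doc.text)
    out = []
    for i, sent in enumerate(doc.sentences):
        ts = normalize_sentence(sent, stopwords)
        ts.source_index = i
        out.append(ts)
    return out
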