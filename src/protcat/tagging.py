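"""Evidence-sentence tagging by protein feature dictionary matching.

For a (document, accession) pair, every sentence mentioning one of the
accession's name strings (entry name, protein names, gene names and
synonyms) — optionally widened to the k nearest neighbouring sentences —
is pooled into a "positive" sub-document; the remaining sentences form
the "negative" sub-document.  When no string matches anywhere, the whole
document is taken as positive (fallback).  The two sub-documents give the
classifier accession-specific views of a single publication.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .data_model import AnnotationExample, Document, ProteinFeatureSet
from .preprocessing import preprocess_document

__all__ = [
    "TaggedPair",
    "build_search_strings",
    "match_sentences",
    "expand_window",
    "tag_pair",
    "tag_corpus",
]

logger = logging.getLogger(__name__)


@dataclass
class TaggedPair:
    """Accession-specific positive/negative partition of one document."""

    doc_id: str
    accession: str
    positive_indices: list[int]
    negative_indices: list[int]
    positive_doc: list[str] = field(default_factory=list)
    negative_doc: list[str] = field(default_factory=list)
    fallback_used: bool = False
    k: int = 0


def build_search_strings(features: ProteinFeatureSet) -> list[str]:
    """Ordered, deduplicated search strings; entries shorter than 2 dropped."""
    strings = [s for s in features.searchable_strings if len(s) >= 2]
    if not strings:
        raise ValueError(f"accession {features.accession!r} has no searchable strings")
    return strings


def _boundary_pattern(strings: list[str]) -> re.Pattern:
    # one alternation, longest first so overlapping names resolve greedily
    alts = sorted((re.escape(s) for s in strings), key=len, reverse=True)
    return re.compile(
        r"(?<![A-Za-z0-9])(?:" + "|".join(alts) + r")(?![A-Za-z0-9])",
        re.IGNORECASE,
    )


def match_sentences(
    sentences: list[str], search_strings: list[str], boundary: bool = True
) -> set[int]:
    """Indices of raw sentences containing any search string.

    Matching is case-insensitive and runs on the raw sentence text.  With
    ``boundary=True`` (default) the match must be flanked by
    non-alphanumeric characters or the sentence edge, which avoids e.g.
    "Il-2" firing inside "Il-23"; ``boundary=False`` is a pure substring
    mode.
    """
    if not search_strings:
        return set()
    if boundary:
        pat = _boundary_pattern(search_strings)
        return {i for i, s in enumerate(sentences) if pat.search(s)}
    lowered = [s.lower() for s in search_strings]
    return {i for i, s in enumerate(sentences) if any(t in s.lower() for t in lowered)}


def expand_window(matched: set[int], k: int, n_sentences: int) -> set[int]:
    """Union of the [i-k, i+k] neighbourhoods of the matched indices."""
    if k < 0:
        raise ValueError("k must be non-negative")
    out: set[int] = set()
    for i in matched:
        out.update(range(max(0, i - k), min(n_sentences, i + k + 1)))
    return out


def tag_pair(
    doc: Document,
    features: ProteinFeatureSet | None,
    k: int = 0,
    stopwords=None,
    boundary: bool = True,
) -> TaggedPair:
    """Build the positive/negative sub-documents for one (doc, accession) pair.

    ``features=None`` forces the whole-document fallback (used when no
    feature set is available for an accession).
    """
    tokenized = preprocess_document(doc, stopwords)
    n = len(doc.sentences)
    if n == 0:
        raise ValueError(f"document {doc.doc_id!r} has no sentences")

    accession = features.accession if features is not None else ""
    if features is not None:
        matched = match_sentences(doc.sentences, build_search_strings(features), boundary)
    else:
        matched = set()

    fallback = not matched
    positive = set(range(n)) if fallback else expand_window(matched, k, n)
    negative = set(range(n)) - positive

    pos_idx, neg_idx = sorted(positive), sorted(negative)
    return TaggedPair(
        doc_id=doc.doc_id,
        accession=accession,
        positive_indices=pos_idx,
        negative_indices=neg_idx,
        positive_doc=[t for i in pos_idx for t in tokenized[i].tokens],
        negative_doc=[t for i in neg_idx for t in tokenized[i].tokens],
        fallback_used=fallback,
        k=k,
    )


def tag_corpus(
    docs: list[Document],
    features_map: dict[str, ProteinFeatureSet],
    annotations: list[AnnotationExample],
    k: int = 0,
    stopwords=None,
    boundary: bool = True,
) -> list[TaggedPair]:
    """One TaggedPair per annotation example, in input order.

    A missing feature set degrades to the whole-document fallback with a
    warning; a missing document is an error.
    """
    by_id = {d.doc_id: d for d in docs}
    pairs: list[TaggedPair] = []
    for ex in annotations:
        if ex.doc_id not in by_id:
            raise KeyError(f"annotation references unknown document {ex.doc_id!r}")
        features = features_map.get(ex.accession)
        if features is None:
            logger.warning(
                "no feature set for accession %s; using whole-document fallback",
                ex.accession,
            )
        pair = tag_pair(by_id[ex.doc_id], features, k=k, stopwords=stopwords, boundary=boundary)
        pair.accession = ex.accession
        pairs.append(pair)
    return pairs
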