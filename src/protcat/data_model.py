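"""Core types, corpus readers/writers and the group-constrained split.

The corpus is exchanged in three plain-text files: ``documents.jsonl``
(one ``{"id", "text", "is_full_text"}`` object per line), ``features.tsv``
(per-accession protein/gene name strings, pipe-separated multi-value
cells) and ``annotations.tsv`` (one ``doc_id, accession, categories``
example per row).  A classified publication is always handled as a
(document, accession) *pair*: the same publication may carry different
category sets for different protein accessions.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Category",
    "N_CATEGORIES",
    "Document",
    "ProteinFeatureSet",
    "AnnotationExample",
    "SplitAssignment",
    "read_documents",
    "write_documents",
    "read_feature_sets",
    "write_feature_sets",
    "read_annotations",
    "write_annotations",
    "read_split",
    "write_split",
    "group_split",
]


class Category(enum.IntEnum):
    """The 11 knowledge-base entry categories, in canonical order.

    The integer value is the category's fixed position in every output
    vector and score matrix.
    """

    EXPRESSION = 0
    FAMILY_DOMAINS = 1
    FUNCTION = 2
    INTERACTION = 3
    NAMES = 4
    PATHOLOGY_BIOTECH = 5
    PTM_PROCESSING = 6
    SEQUENCES = 7
    STRUCTURE = 8
    SUBCELLULAR_LOCATION = 9
    MISCELLANEOUS = 10

    @property
    def label(self) -> str:
        return _LABELS[self.value]

    @classmethod
    def from_label(cls, label: str) -> "Category":
        try:
            return _LABEL_TO_CATEGORY[label.strip().lower()]
        except KeyError:
            raise ValueError(f"unknown category label: {label!r}") from None


_LABELS = [
    "Expression",
    "Family & Domains",
    "Function",
    "Interaction",
    "Names",
    "Pathology & Biotech",
    "PTM/Processing",
    "Sequences",
    "Structure",
    "Subcellular Location",
    "Miscellaneous",
]

_LABEL_TO_CATEGORY = {lab.lower(): Category(i) for i, lab in enumerate(_LABELS)}

N_CATEGORIES = len(Category)


@dataclass
class Document:
    doc_id: str
    text: str
    sentences: list[str] = field(default_factory=list)
    is_full_text: bool = False

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")


def _dedup(strings) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for s in strings:
        if s and s not in seen:
            seen.add(s)
            out.append(s)
    return out


@dataclass
class ProteinFeatureSet:
    """Searchable name strings for one accession.

    ``names`` holds recommended, alternative and short protein names;
    ``genes`` the gene name and its synonyms — the strings shown in the
    knowledge base's "Names & Taxonomy" section.
    """

    accession: str
    entry_name: str = ""
    names: list[str] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")

    @property
    def searchable_strings(self) -> list[str]:
        """Deduplicated, order-preserving entry_name + names + genes."""
        return _dedup([self.entry_name, *self.names, *self.genes])


@dataclass(frozen=True)
class AnnotationExample:
    doc_id: str
    accession: str
    categories: frozenset[Category]

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError(
                f"empty category set for ({self.doc_id}, {self.accession})"
            )
        object.__setattr__(self, "categories", frozenset(self.categories))


PARTITIONS = ("train", "validation", "test")


@dataclass
class SplitAssignment:
    assignment: dict[str, str]
    fractions: tuple[float, float, float]
    seed: int

    def partition(self, doc_id: str) -> str:
        return self.assignment[doc_id]

    def doc_ids(self, partition: str) -> list[str]:
        return [d for d, p in self.assignment.items() if p == partition]


# ---------------------------------------------------------------------------
# readers / writers


def read_documents(path: str | Path) -> list[Document]:
    """Read a JSONL document file ({"id", "text", optional "is_full_text"})."""
    docs: list[Document] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                doc_id, text = str(rec["id"]), rec["text"]
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise ValueError(f"malformed document record at line {lineno}: {exc}")
            if doc_id in seen:
                raise ValueError(f"duplicate doc_id {doc_id!r} at line {lineno}")
            seen.add(doc_id)
            docs.append(
                Document(doc_id, text, is_full_text=bool(rec.get("is_full_text", False)))
            )
    return docs


def write_documents(docs: list[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(
                json.dumps(
                    {"id": doc.doc_id, "text": doc.text, "is_full_text": doc.is_full_text}
                )
                + "\n"
            )


def _read_tsv(path: str | Path, required: list[str]):
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for col in required:
            if col not in header:
                raise ValueError(f"missing column {col!r} in {path}")
        idx = {col: header.index(col) for col in required}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) < len(header):
                raise ValueError(f"short row at line {lineno} in {path}")
            yield lineno, {col: cells[i] for col, i in idx.items()}


def _split_pipe(cell: str) -> list[str]:
    return [part for part in cell.split("|") if part]


def read_feature_sets(path: str | Path) -> dict[str, ProteinFeatureSet]:
    """Read the per-accession feature TSV (pipe-separated name cells)."""
    out: dict[str, ProteinFeatureSet] = {}
    cols = ["accession", "entry_name", "protein_names", "gene_names"]
    for lineno, row in _read_tsv(path, cols):
        acc = row["accession"]
        if acc in out:
            raise ValueError(f"duplicate accession {acc!r} at line {lineno}")
        out[acc] = ProteinFeatureSet(
            accession=acc,
            entry_name=row["entry_name"],
            names=_split_pipe(row["protein_names"]),
            genes=_split_pipe(row["gene_names"]),
        )
    return out


def write_feature_sets(features: dict[str, ProteinFeatureSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("accession\tentry_name\tprotein_names\tgene_names\n")
        for fs in features.values():
            fh.write(
                f"{fs.accession}\t{fs.entry_name}\t{'|'.join(fs.names)}\t{'|'.join(fs.genes)}\n"
            )


def read_annotations(path: str | Path) -> list[AnnotationExample]:
    """Read (doc_id, accession, categories) examples; labels must be canonical."""
    out: list[AnnotationExample] = []
    seen: set[tuple[str, str]] = set()
    for lineno, row in _read_tsv(path, ["doc_id", "accession", "categories"]):
        labels = _split_pipe(row["categories"])
        if not labels:
            raise ValueError(f"empty category cell at line {lineno}")
        key = (row["doc_id"], row["accession"])
        if key in seen:
            raise ValueError(f"duplicate (doc_id, accession) pair {key} at line {lineno}")
        seen.add(key)
        out.append(
            AnnotationExample(
                doc_id=row["doc_id"],
                accession=row["accession"],
                categories=frozenset(Category.from_label(lab) for lab in labels),
            )
        )
    return out


def write_annotations(examples: list[AnnotationExample], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("doc_id\taccession\tcategories\n")
        for ex in examples:
            labels = "|".join(c.label for c in sorted(ex.categories))
            fh.write(f"{ex.doc_id}\t{ex.accession}\t{labels}\n")


def read_split(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, row in _read_tsv(path, ["doc_id", "partition"]):
        if row["partition"] not in PARTITIONS:
            raise ValueError(f"unknown partition at line {lineno}: {row['partition']!r}")
        out[row["doc_id"]] = row["partition"]
    return out


def write_split(split: SplitAssignment, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("doc_id\tpartition\n")
        for doc_id, part in split.assignment.items():
            fh.write(f"{doc_id}\t{part}\n")


# ---------------------------------------------------------------------------
# group-constrained split


DEFAULT_FRACTIONS = (0.762, 0.117, 0.121)


def group_split(
    examples: list[AnnotationExample],
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> SplitAssignment:
    """Randomly divide documents into train/validation/test partitions.

    All examples of one document land in the same partition (a publication
    annotated for several proteins must not leak across sets).  Documents
    are shuffled with ``seed`` and assigned greedily, filling each
    partition's example-count budget in turn, so the realized
    *example-level* fractions approach the targets up to whole-document
    rounding.
    """
    if any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")

    counts: dict[str, int] = {}
    for ex in examples:
        counts[ex.doc_id] = counts.get(ex.doc_id, 0) + 1
    doc_ids = sorted(counts)
    if len(doc_ids) < len(PARTITIONS):
        raise ValueError(
            f"need at least {len(PARTITIONS)} distinct documents, got {len(doc_ids)}"
        )

    rng = np.random.default_rng(seed)
    order = [doc_ids[i] for i in rng.permutation(len(doc_ids))]

    total = len(examples)
    budgets = [f * total for f in fractions]
    assignment: dict[str, str] = {}
    part_idx = 0
    filled = 0.0
    for doc_id in order:
        assignment[doc_id] = PARTITIONS[part_idx]
        filled += counts[doc_id]
        # advance once this partition's example budget is met (last absorbs rest)
        while part_idx < len(PARTITIONS) - 1 and filled >= budgets[part_idx]:
            filled -= budgets[part_idx]
            part_idx += 1
    return SplitAssignment(assignment=assignment, fractions=tuple(fractions), seed=seed)
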