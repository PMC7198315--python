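# protcat

Multi-label categorization of publication–protein pairs for knowledge-base
curation.

## The problem

Protein knowledge bases file the publications attached to each protein
entry under 11 topical categories — Expression, Family & Domains,
Function, Interaction, Names, Pathology & Biotech, PTM/Processing,
Sequences, Structure, Subcellular Location and Miscellaneous. The
classification unit is not the publication but the **(publication,
accession) pair**: one paper annotated for several proteins usually
carries a *different* category set for each of them. A standard document
classifier cannot express this — it sees the same input text with
conflicting labels.

`protcat` implements the evidence-tagging strategy that resolves the
ambiguity. For a pair (d, a), every sentence of document *d* that
mentions one of accession *a*'s name strings (entry name, recommended /
alternative / short protein names, gene name and synonyms), widened to
the *k* nearest sentences (default *k* = 0), is pooled into a
**positive** sub-document d⁺; the remaining sentences form the
**negative** sub-document d⁻. If no string matches, the whole document
falls back to d⁺. The classifier then scores

&nbsp;&nbsp;&nbsp;&nbsp;P(c | d, a) = f(d⁺(a), d⁻(a)),&nbsp;&nbsp;c ∈ {1, …, 11},

so two accessions of the same paper get different inputs. Three model
families are provided, each in a *tagged* (d⁺/d⁻) and a *not-tagged*
(whole-document) version:

* logistic regression and linear SVM on paragraph-vector features —
  DBOW‖DMC embeddings of 200 dimensions each: 400-d per document, 800-d
  per tagged pair (400 for d⁺, 400 for d⁻);
* a dual-branch CNN: per branch, a trainable embedding layer (input
  width 1500, initialized from the trained DBOW word vectors) feeding
  three convolutional layers (128 channels, kernel width 5, ReLU, batch
  normalization), global max-pooling and dropout 0.5; the pooled branch
  outputs are concatenated into a dense layer (width 128) and an 11-way
  output layer. Training runs at most 50 epochs with early stopping
  after 5 epochs without validation improvement.

The text pipeline (sentence splitting, lowercasing, stopword removal,
Porter stemming, removal of tokens shorter than two characters, masking
of numeric tokens as `_NUMBER_`), the paragraph-vector trainer and the
CNN (with exact backprop) are implemented here in numpy; linear models
use scikit-learn. A seeded synthetic-corpus generator reproduces the
statistical structure of curated bibliographies — several accessions per
document, accession-specific evidence sentences carrying
category-specific vocabulary, identical documents with different label
sets — so the whole method is testable end to end without downloading
any corpus.

## Worked example

```python
from protcat import Document, ProteinFeatureSet, tag_pair

doc = Document(
    "d1",
    "Background about cells. PTTG1 is overexpressed in tumors. "
    "Methods were standard.",
)
securin = ProteinFeatureSet(
    accession="O95997", entry_name="PTTG1_HUMAN",
    names=["Securin", "hPTTG"], genes=["PTTG1", "EAP1", "PTTG", "TUTR1"],
)
pair = tag_pair(doc, securin, k=0)
print(pair.positive_indices, pair.negative_indices, pair.fallback_used)
print(pair.positive_doc)
```

prints

```
[1] [0, 2] False
['pttg1', 'overexpress', 'tumor']
```

— sentence 1 mentions the gene name `PTTG1`, so it alone forms the
positive sub-document (already normalized: lowercased, stemmed,
stopwords removed); sentences 0 and 2 form the negative one.

The full pipeline on a synthetic ambiguity corpus (~500 pairs, one
seed):

```python
from protcat.pipeline import run_comparison
res = run_comparison(seed=1)
print(round(res["tagged"]["macro_f1"], 3), round(res["not_tagged"]["macro_f1"], 3))
```

prints `0.182 0.082`: the tagged CNN recovers accession-specific
category sets that the whole-document model structurally cannot, and its
macro F1 is higher — the direction the dual-branch design predicts.

A command-line interface covers the same stages:

```bash
protcat simulate --n-documents 100 --seed 13 --out corpus/
protcat split --annotations corpus/annotations.tsv --seed 1 --out splits.tsv
protcat tag --documents corpus/documents.jsonl --features corpus/features.tsv \
            --annotations corpus/annotations.tsv --k 0 --out tagged.jsonl
protcat embed --documents corpus/documents.jsonl --variant DBOW --out dbow.npz
```

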