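# Methods

## Task and model

The unit of classification is a (publication, protein accession) pair;
the output is a non-empty subset of 11 fixed entry categories
(Expression, Family & Domains, Function, Interaction, Names, Pathology &
Biotech, PTM/Processing, Sequences, Structure, Subcellular Location,
Miscellaneous; this order indexes every score vector). Because one
publication is typically annotated for several proteins with different
category sets, the document text alone cannot determine the label set.
The model therefore conditions on the accession through *evidence
tagging*: sentences that mention any of the accession's name strings are
concatenated into a positive sub-document, the rest into a negative one,
and the two parts are classified jointly.

### Evidence tagging

Name strings come from the per-accession feature set (entry name,
protein names, gene names and synonyms). Matching is case-insensitive
substring search on the **raw** sentence text — normalization would
destroy strings such as `PTTG1_HUMAN` — with a word-boundary constraint
on both ends (boundary = sentence edge or a non-alphanumeric character).
The boundary rule reduces collisions among numbered protein names
(`Il-2` inside `Il-23`); a pure substring mode remains available as a
flag for fidelity experiments, since boundary behaviour of the original
method is not documented. Strings shorter than two characters are
dropped (they match near-everything). Matched sentence indices are
expanded to the k nearest neighbours (default k = 0, a tunable
parameter); if no sentence matches at all, the whole document becomes
the positive part (`fallback_used`). Fallback is decided on the raw
match count, before window expansion. Tagging never sees the labels, so
no leakage is possible by construction.

### Preprocessing

Sentence boundaries are found by a rule-based detector for English
scientific prose: a run of `.!?` followed by whitespace and an
uppercase/digit/bracket opener, vetoed after common abbreviations and
single initials. Tokens are maximal alphanumeric runs; normalization
applies, in order, lowercasing, stopword removal (standard 179-word
English list, shipped as a plain-text resource and overridable;
matching happens on unstemmed forms), Porter stemming of alphabetic
tokens, removal of tokens shorter than two characters, and replacement
of all-digit tokens by `_NUMBER_`. The step order matters and is pinned
by a frozen worked-example fixture: e.g. `min(-1)` contributes no
`_NUMBER_` because the isolated digit dies in the length filter first,
while `0.066` does (`066` survives and is masked). The Porter stemmer
implements the classic algorithm with the author's later revision of
step 1c (terminal `y` → `i` only after a non-initial consonant), which
the fixture requires (`displaying` → `display`, `study` → `studi`).
Mixed alphanumeric tokens (`il2`) are never masked: the mask replaces
numerical sequences only.

### Embeddings

Paragraph vectors are trained with negative sampling (5 negatives,
unigram^0.75 noise distribution, linearly decaying learning rate from
0.025): DBOW predicts a document's words from its document vector; DMC
predicts a centre word from the concatenation of the document vector
and the window word vectors (missing context positions contribute zero
vectors). Defaults follow the study configuration: vector size 200,
window 10, 100 epochs, minimum token count 2 (prunes hapax noise in
small corpora). Held-out documents are embedded by gradient inference
against frozen weights — never by inclusion in training — and empty or
fully out-of-vocabulary documents embed to the zero vector. A document
is represented by DBOW‖DMC (400 dims); a tagged pair by the positive
then negative sub-document embeddings (800 dims). The DBOW output
matrix doubles as the word representation used to initialize the CNN
embedding layer.

### Classifiers

Linear baselines are one-vs-rest logistic regression and linear SVM
(scikit-learn) on the 400-/800-d features; SVM margins are squashed to
[0, 1] by a logistic function so both families expose thresholdable
scores. Categories lacking both a positive and a negative training
example are skipped with a warning and score their observed constant.

The CNN has one branch per input part (two weight-independent branches
in tagged mode, one in not-tagged mode): embedding lookup (input width
1500, head truncation, right padding with a reserved id-0 row; unknown
tokens map to a zero-initialized UNK row; all rows trainable) → three
blocks of [convolution (128 channels, kernel 5, valid padding) + ReLU +
batch normalization] → global max pooling → dropout 0.5. Pooled branch
outputs are concatenated (256 in tagged mode, 128 otherwise) into a
ReLU dense layer of width 128 and an output layer of width 11. Batch
normalization is applied per convolutional layer. The default output is
sigmoid with binary cross-entropy, since independent per-category
probabilities are what a multi-label decision needs; a softmax +
label-normalized categorical cross-entropy mode is selectable for
architectural fidelity, with default threshold 1/11 instead of 0.5.
Predicted sets are `{c : score_c ≥ τ}` with an argmax backstop so no
prediction is empty. Optimization is mini-batch Adam with early
stopping on validation loss (at most 50 epochs, patience 5,
best-epoch weights restored); forward, backward and the optimizer are
implemented in numpy (float32) and verified against numerical
differentiation.

Two numerical choices depart from a naive transcription and matter on
short, heavily padded inputs:

* **masked statistics and pooling** — convolution windows that lie
  entirely in the padding tail are excluded from batch-norm statistics
  and from the global max pool (the backward pass accounts for the
  masked statistics exactly). Without this, the constant activations of
  the padding tail dominate both the normalization statistics and the
  pooled features;
* **embedding-init rescaling** — DBOW word vectors trained on a small
  corpus have tiny norms; the initializer matrix is rescaled to element
  standard deviation 0.05 (a standard embedding-init magnitude),
  preserving the learned directions while keeping the first
  convolution's activations away from the degenerate near-zero regime
  that batch normalization amplifies.

### Data handling

Corpora are exchanged as JSONL documents plus TSV feature and
annotation tables (pipe-separated multi-value cells, mirroring flat
knowledge-base exports). The train/validation/test split (default
fractions 0.762/0.117/0.121) shuffles whole documents with a seed and
fills each partition's example budget greedily, so no document's
examples ever straddle partitions; realized example-level fractions
converge to the targets up to whole-document rounding. Splitting is not
stratified by category — the original division is described only as
random under the group constraint. Evaluation offers micro metrics
(pooled per-decision counts), macro metrics (unweighted over categories
present in the gold standard, with absent ones listed explicitly),
per-category precision-recall sweeps with step-wise (non-interpolated)
average precision where tied scores form a single sweep point, a
seeded deduplication that keeps one random representative per
(document, gold category set) group, and a paired two-sided t-test on
per-sample F1 (paired because both models score the same samples;
zero-variance differences are flagged degenerate rather than tested).

## Synthetic corpus generator

The generator emulates the structure the method exploits, with all
randomness drawn from one seed:

* each document carries 1–4 accessions (configurable); each accession
  draws an independent category set (per-category inclusion probability
  `label_prior`, resampled to be non-empty);
* each accession owns at least one *evidence sentence* containing one
  of its generated name strings verbatim plus, with probability
  `signal_strength` per gold category, a category-specific signal
  token; remaining sentences are either further evidence sentences or
  pure background (`noise_rate`);
* signal tokens and background words are random alphabetic strings that
  are Porter-stemming fixed points and not stopwords, so they pass the
  normalization pipeline unchanged; generated protein names use an
  uppercase+digit alphabet disjoint from the background vocabulary, so
  dictionary matches occur exactly where the construction placed them;
* with ≥10 documents, the last document duplicates the first's text
  verbatim with independently redrawn category sets for the same
  accessions — the canonical case of identical input with
  accession-dependent labels (these `relabeled` annotations are the one
  place where labels are deliberately decoupled from the text);
* an `untaggable_fraction` omits an annotation's names from the text,
  exercising the whole-document fallback.

With `signal_strength=1, noise_rate=0, k=0` the tagger provably
recovers the generating truth exactly, which the tests assert. What the
generator does **not** emulate: real biomedical vocabulary and
morphology, the heavy class imbalance of curated collections, noisy or
partial name mentions (abbreviations, orthographic variants), and
full-text document length. Passing tests therefore demonstrate the
correctness of the machinery and the direction of the tagged-model
advantage under controlled conditions, not absolute performance on real
curation data.

## Study sizes and scaled defaults

The experiment driver (`protcat.pipeline`) uses a scaled study design
chosen so a full comparison runs in about a minute on one CPU: a
200-document ambiguity corpus (2–3 accessions per document, ≈500
examples, 4–6 sentences of 4–7 tokens), CNN input width 64 → 48 tokens,
batch size 16, learning rate 5·10⁻⁴, at most 60 epochs with patience 8,
and DBOW initialization trained for 20 epochs with window 3. At this
scale the whole-document model faces many identical inputs with
conflicting labels and cannot exceed per-document marginal predictions,
while the tagged model can; the comparison is repeated over 5 seeds and
decided by majority. Full-size defaults (input width 1500, 100-epoch
embeddings, window 10, 50-epoch CNN training) remain the configuration
defaults for real corpora.

## Known limitations

* The rule-based sentence splitter approximates an unsupervised
  boundary model; rare abbreviation patterns can over- or under-split.
* Dictionary matching cannot resolve names that normalization removed
  (tokens shorter than two characters) or that appear only as variants
  not listed in the feature set.
* The numpy CNN is single-threaded and intended for method validation
  and moderate corpus sizes, not production-scale training.
* Paired t-tests on per-sample F1 treat samples as independent, which
  publications annotated for many proteins violate; the deduplication
  protocol mitigates but does not remove this.
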