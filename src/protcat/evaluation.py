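"""Multi-label evaluation: micro/macro P/R/F1, AP, dedup, model comparison.

Micro metrics pool true/false positive/negative decisions over every
(sample, category) cell; macro metrics average per-category scores
unweighted, over the categories actually present in the gold standard.
Also provides the unique-(document, category-set) deduplication used to
de-bias test collections, the per-category precision-recall sweep with
average precision, a paired t-test between two models' per-sample F1
scores, and the sentence-level scorer for the evidence tagger.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import Category, N_CATEGORIES

__all__ = [
    "MetricReport",
    "multilabel_metrics",
    "per_sample_f1",
    "dedup_unique",
    "pr_curve_map",
    "compare_models",
    "tagging_eval",
]


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


@dataclass
class MetricReport:
    micro_precision: float
    micro_recall: float
    micro_f1: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_category: dict[Category, tuple[float, float, float]]
    excluded_categories: list[Category]
    n_samples: int
    average_precision: dict[Category, float] = field(default_factory=dict)

    @property
    def mean_average_precision(self) -> float:
        if not self.average_precision:
            return float("nan")
        return float(np.mean(list(self.average_precision.values())))


def multilabel_metrics(
    gold: list[frozenset[Category]], predicted: list[frozenset[Category]]
) -> MetricReport:
    """Micro and macro precision/recall/F1 over the 11 categories.

    Categories with no gold occurrence are excluded from the macro
    averages and listed in ``excluded_categories``.
    """
    if len(gold) != len(predicted):
        raise ValueError("gold and predicted must have equal length")
    tp = np.zeros(N_CATEGORIES, dtype=np.int64)
    fp = np.zeros(N_CATEGORIES, dtype=np.int64)
    fn = np.zeros(N_CATEGORIES, dtype=np.int64)
    gold_count = np.zeros(N_CATEGORIES, dtype=np.int64)
    for g, p in zip(gold, predicted):
        for c in g:
            gold_count[int(c)] += 1
            if c in p:
                tp[int(c)] += 1
            else:
                fn[int(c)] += 1
        for c in p - g:
            fp[int(c)] += 1

    micro = _prf(int(tp.sum()), int(fp.sum()), int(fn.sum()))
    per_cat = {Category(c): _prf(int(tp[c]), int(fp[c]), int(fn[c]))
               for c in range(N_CATEGORIES)}
    present = [c for c in range(N_CATEGORIES) if gold_count[c] > 0]
    excluded = [Category(c) for c in range(N_CATEGORIES) if gold_count[c] == 0]
    if present:
        macro = tuple(
            float(np.mean([per_cat[Category(c)][i] for c in present])) for i in range(3)
        )
    else:
        macro = (0.0, 0.0, 0.0)
    return MetricReport(
        micro_precision=micro[0], micro_recall=micro[1], micro_f1=micro[2],
        macro_precision=macro[0], macro_recall=macro[1], macro_f1=macro[2],
        per_category=per_cat, excluded_categories=excluded, n_samples=len(gold),
    )


def per_sample_f1(
    gold: list[frozenset[Category]], predicted: list[frozenset[Category]]
) -> np.ndarray:
    """F1 of each sample's predicted label set against its gold set."""
    if len(gold) != len(predicted):
        raise ValueError("gold and predicted must have equal length")
    out = np.zeros(len(gold))
    for i, (g, p) in enumerate(zip(gold, predicted)):
        tp = len(g & p)
        denom = len(g) + len(p)
        out[i] = 2 * tp / denom if denom else 1.0
    return out


def dedup_unique(examples: list, predictions: list | None = None, seed: int = 0):
    """Keep one random (document, gold category set) representative.

    Publications annotated for several accessions with the same category
    set contribute correlated samples; all but one randomly chosen
    representative per (doc_id, category set) group are suppressed.
    Returns (kept_examples, kept_predictions, reduction_ratio); kept
    order follows the input order of the surviving indices.
    """
    if predictions is not None and len(predictions) != len(examples):
        raise ValueError("examples and predictions must align")
    groups: dict[tuple, list[int]] = {}
    for i, ex in enumerate(examples):
        groups.setdefault((ex.doc_id, frozenset(ex.categories)), []).append(i)
    rng = np.random.default_rng(seed)
    keep = sorted(
        members[int(rng.integers(len(members)))]
        for _, members in sorted(groups.items(), key=lambda kv: (kv[0][0], sorted(map(int, kv[0][1]))))
    )
    kept_examples = [examples[i] for i in keep]
    kept_predictions = [predictions[i] for i in keep] if predictions is not None else None
    ratio = 1.0 - len(keep) / len(examples) if examples else 0.0
    return kept_examples, kept_predictions, ratio


def pr_curve_map(
    gold: list[frozenset[Category]],
    scores: np.ndarray,
    category: Category,
) -> tuple[list[tuple[float, float]], float]:
    """Precision-recall sweep and (step-wise) average precision for one category.

    Samples are swept by descending score; tied scores form a single
    sweep point.  AP = sum over sweep points of (R_i - R_{i-1}) * P_i.
    Raises if the category has no gold positives (undefined AP).
    """
    y = np.array([1 if category in g else 0 for g in gold])
    s = np.asarray(scores, dtype=np.float64)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError(f"category {category.label!r} has no gold positives; AP undefined")
    order = np.argsort(-s, kind="stable")
    y_sorted, s_sorted = y[order], s[order]
    points: list[tuple[float, float]] = []
    ap = 0.0
    prev_recall = 0.0
    tp = 0
    i = 0
    n = len(y_sorted)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            j += 1
        tp += int(y_sorted[i:j].sum())
        precision = tp / j
        recall = tp / n_pos
        points.append((recall, precision))
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return points, ap


def compare_models(
    scores_a: np.ndarray, scores_b: np.ndarray, alpha: float = 0.05
) -> dict:
    """Paired two-sided t-test on aligned per-sample quality scores.

    Returns statistic, p-value, significance flag at ``alpha`` and a
    ``degenerate`` flag when the paired differences have zero variance
    (identical or constant-offset score vectors).
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score vectors must be 1-d and aligned")
    if a.size < 2:
        raise ValueError("need at least 2 paired samples")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        identical = bool(np.allclose(diff, 0.0))
        return {
            "statistic": float("nan"),
            "p_value": 1.0 if identical else 0.0,
            "significant": not identical,
            "degenerate": True,
            "mean_difference": float(diff.mean()),
        }
    t, p = stats.ttest_rel(a, b)
    return {
        "statistic": float(t),
        "p_value": float(p),
        "significant": bool(p < alpha),
        "degenerate": False,
        "mean_difference": float(diff.mean()),
    }


def tagging_eval(
    gold_positive: list[set[int]], predicted_positive: list[set[int]]
) -> dict:
    """Micro precision/recall of predicted evidence-sentence index sets.

    Counts are pooled over documents: P = |intersection| / |predicted|,
    R = |intersection| / |gold|.  An empty pooled prediction set leaves
    precision undefined (None) with a flag.
    """
    if len(gold_positive) != len(predicted_positive):
        raise ValueError("gold and predicted must align per document")
    inter = sum(len(set(g) & set(p)) for g, p in zip(gold_positive, predicted_positive))
    n_pred = sum(len(set(p)) for p in predicted_positive)
    n_gold = sum(len(set(g)) for g in gold_positive)
    return {
        "precision": inter / n_pred if n_pred else None,
        "recall": inter / n_gold if n_gold else 0.0,
        "n_matched": inter,
        "n_predicted": n_pred,
        "n_gold": n_gold,
        "precision_undefined": n_pred == 0,
    }
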