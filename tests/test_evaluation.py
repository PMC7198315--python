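import numpy as np
import pytest

from protcat.data_model import AnnotationExample, Category
from protcat.evaluation import (
    compare_models,
    dedup_unique,
    multilabel_metrics,
    per_sample_f1,
    pr_curve_map,
    tagging_eval,
)

from .conftest import random_label_set

F, I, M, S = Category.FUNCTION, Category.INTERACTION, Category.MISCELLANEOUS, Category.SEQUENCES


def brute_force_metrics(gold, predicted):
    """Independent per-decision 2x2 tally over every (sample, category) cell."""
    tp = {c: 0 for c in Category}
    fp = {c: 0 for c in Category}
    fn = {c: 0 for c in Category}
    for g, p in zip(gold, predicted):
        for c in Category:
            if c in g and c in p:
                tp[c] += 1
            elif c in p:
                fp[c] += 1
            elif c in g:
                fn[c] += 1

    def prf(tp_, fp_, fn_):
        pr = tp_ / (tp_ + fp_) if tp_ + fp_ else 0.0
        rc = tp_ / (tp_ + fn_) if tp_ + fn_ else 0.0
        f1 = 2 * pr * rc / (pr + rc) if pr + rc else 0.0
        return pr, rc, f1

    micro = prf(sum(tp.values()), sum(fp.values()), sum(fn.values()))
    present = [c for c in Category if any(c in g for g in gold)]
    percat = {c: prf(tp[c], fp[c], fn[c]) for c in present}
    macro = tuple(np.mean([percat[c][i] for c in present]) for i in range(3))
    return micro, macro


def brute_force_ap(y, scores):
    """Sweep by descending score, tied scores as one point."""
    order = sorted(set(scores), reverse=True)
    n_pos = sum(y)
    ap, prev_r, kept = 0.0, 0.0, 0
    tp = 0
    for thr in order:
        sel = [i for i, s in enumerate(scores) if s >= thr]
        tp = sum(y[i] for i in sel)
        p = tp / len(sel)
        r = tp / n_pos
        ap += (r - prev_r) * p
        prev_r = r
    return ap


class TestMultilabelMetrics:
    def test_perfect_prediction(self):
        rep = multilabel_metrics([frozenset({F})], [frozenset({F})])
        assert rep.micro_f1 == rep.macro_f1 == 1.0

    def test_hand_counted_partial(self):
        rep = multilabel_metrics([frozenset({F, I})], [frozenset({F})])
        assert rep.micro_precision == 1.0
        assert rep.micro_recall == 0.5
        assert rep.micro_f1 == pytest.approx(2 / 3)

    def test_total_miss_on_distinct_singletons(self):
        rep = multilabel_metrics(
            [frozenset({F}), frozenset({I})], [frozenset({I}), frozenset({F})]
        )
        assert rep.micro_f1 == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            multilabel_metrics([frozenset({F})], [])

    def test_micro_f1_is_harmonic_mean(self, rng):
        gold = [random_label_set(rng) for _ in range(50)]
        pred = [random_label_set(rng) for _ in range(50)]
        rep = multilabel_metrics(gold, pred)
        if rep.micro_precision + rep.micro_recall:
            hm = (2 * rep.micro_precision * rep.micro_recall
                  / (rep.micro_precision + rep.micro_recall))
            assert rep.micro_f1 == pytest.approx(hm)

    def test_agrees_with_brute_force_tally(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 15))
            gold = [random_label_set(rng) for _ in range(n)]
            pred = [random_label_set(rng) for _ in range(n)]
            rep = multilabel_metrics(gold, pred)
            micro, macro = brute_force_metrics(gold, pred)
            assert (rep.micro_precision, rep.micro_recall, rep.micro_f1) == pytest.approx(micro)
            assert (rep.macro_precision, rep.macro_recall, rep.macro_f1) == pytest.approx(macro)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import precision_recall_fscore_support

        gold = [random_label_set(rng) for _ in range(80)]
        pred = [random_label_set(rng) for _ in range(80)]
        G = np.array([[c in g for c in Category] for g in gold], dtype=int)
        P = np.array([[c in p for c in Category] for p in pred], dtype=int)
        rep = multilabel_metrics(gold, pred)
        p, r, f, _ = precision_recall_fscore_support(G, P, average="micro", zero_division=0)
        assert (rep.micro_precision, rep.micro_recall, rep.micro_f1) == pytest.approx((p, r, f))

    def test_invariant_under_sample_reordering(self, rng):
        gold = [random_label_set(rng) for _ in range(30)]
        pred = [random_label_set(rng) for _ in range(30)]
        rep1 = multilabel_metrics(gold, pred)
        order = rng.permutation(30)
        rep2 = multilabel_metrics([gold[i] for i in order], [pred[i] for i in order])
        assert rep1.micro_f1 == rep2.micro_f1 and rep1.macro_f1 == rep2.macro_f1

    def test_absent_categories_excluded_from_macro(self):
        rep = multilabel_metrics([frozenset({F})] * 4, [frozenset({F})] * 4)
        assert rep.macro_f1 == 1.0
        assert Category.NAMES in rep.excluded_categories
        assert F not in rep.excluded_categories


class TestPerSampleF1:
    def test_values(self):
        out = per_sample_f1(
            [frozenset({F, I}), frozenset({F})], [frozenset({F}), frozenset({I})]
        )
        assert out[0] == pytest.approx(2 / 3)
        assert out[1] == 0.0


class TestDedupUnique:
    def _ex(self, doc, acc, cats):
        return AnnotationExample(doc, acc, frozenset(cats))

    def test_same_set_group_keeps_one(self):
        examples = [self._ex("d1", f"P{i}", {S}) for i in range(3)]
        kept, _, ratio = dedup_unique(examples, seed=0)
        assert len(kept) == 1
        assert ratio == pytest.approx(2 / 3)

    def test_distinct_sets_both_survive(self):
        examples = [self._ex("d1", "P1", {F}), self._ex("d1", "P2", {F, S})]
        kept, _, _ = dedup_unique(examples, seed=0)
        assert len(kept) == 2

    def test_deterministic_and_alignment_preserved(self, rng):
        examples = []
        preds = []
        for d in range(10):
            for a in range(int(rng.integers(1, 4))):
                examples.append(self._ex(f"d{d}", f"P{d}_{a}", random_label_set(rng)))
                preds.append(f"pred{len(preds)}")
        k1, p1, _ = dedup_unique(examples, preds, seed=5)
        k2, p2, _ = dedup_unique(examples, preds, seed=5)
        assert k1 == k2 and p1 == p2
        for ex, pr in zip(k1, p1):
            assert preds[examples.index(ex)] == pr

    def test_never_increases_and_covers_every_group(self, rng):
        examples = [
            self._ex(f"d{int(rng.integers(5))}", f"P{i}", random_label_set(rng, 2))
            for i in range(40)
        ]
        kept, _, _ = dedup_unique(examples, seed=2)
        assert len(kept) <= len(examples)
        assert {(e.doc_id, e.categories) for e in kept} == {
            (e.doc_id, e.categories) for e in examples
        }


class TestPrCurveMap:
    def test_perfect_ranking(self):
        gold = [frozenset({F})] * 3 + [frozenset({I})] * 3
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.05])
        _, ap = pr_curve_map(gold, scores, F)
        assert ap == 1.0

    def test_constant_scores_give_prevalence(self):
        gold = [frozenset({F}), frozenset({F})] + [frozenset({I})] * 3
        points, ap = pr_curve_map(gold, np.full(5, 0.5), F)
        assert points == [(1.0, 0.4)]
        assert ap == pytest.approx(0.4)

    def test_reversed_ranking_single_positive(self):
        gold = [frozenset({I})] * 9 + [frozenset({F})]
        scores = np.linspace(1.0, 0.1, 10)  # positive ranked last
        _, ap = pr_curve_map(gold, scores, F)
        assert ap == pytest.approx(1 / 10)

    def test_no_gold_positives_flagged(self):
        with pytest.raises(ValueError, match="no gold positives"):
            pr_curve_map([frozenset({I})], np.array([0.3]), F)

    def test_non_finite_scores_rejected(self):
        with pytest.raises(ValueError):
            pr_curve_map([frozenset({F})], np.array([np.nan]), F)

    def test_agrees_with_exhaustive_sweep_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 21))
            y = [int(v) for v in (rng.random(n) < 0.4)]
            if not any(y):
                y[0] = 1
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            gold = [frozenset({F}) if v else frozenset({I}) for v in y]
            _, ap = pr_curve_map(gold, scores, F)
            assert ap == pytest.approx(brute_force_ap(y, list(scores)))

    def test_agrees_with_sklearn_average_precision(self, rng):
        from sklearn.metrics import average_precision_score

        for _ in range(50):
            n = int(rng.integers(3, 30))
            y = (rng.random(n) < 0.5).astype(int)
            if y.sum() == 0:
                y[0] = 1
            scores = np.round(rng.random(n), 2)
            gold = [frozenset({F}) if v else frozenset({I}) for v in y]
            _, ap = pr_curve_map(gold, scores, F)
            assert ap == pytest.approx(average_precision_score(y, scores))


class TestCompareModels:
    def test_identical_scores(self):
        out = compare_models(np.ones(10), np.ones(10))
        assert out["degenerate"] and out["p_value"] == 1.0 and not out["significant"]

    def test_constant_offset_flagged_degenerate(self):
        b = np.linspace(0, 1, 100)
        out = compare_models(b + 0.1, b)
        assert out["degenerate"] and out["significant"]
        assert out["mean_difference"] == pytest.approx(0.1)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_models(np.array([1.0]), np.array([0.5]))

    def test_detects_simulated_improvement(self):
        # A ~ B + N(0.05, 0.1^2), n=200: the paired test should almost
        # always reject equality
        rng = np.random.default_rng(99)
        hits = 0
        for _ in range(100):
            b = rng.random(200)
            a = b + rng.normal(0.05, 0.1, 200)
            if compare_models(a, b)["significant"]:
                hits += 1
        assert hits >= 95

    def test_matches_scipy(self, rng):
        from scipy import stats

        a, b = rng.random(50), rng.random(50)
        out = compare_models(a, b)
        t, p = stats.ttest_rel(a, b)
        assert out["statistic"] == pytest.approx(t)
        assert out["p_value"] == pytest.approx(p)


class TestTaggingEval:
    def test_pooled_counts_match_printed_arithmetic(self):
        # pooled: 28 shared sentences, 67 predicted, 61 gold
        gold = [set(range(31)), set(range(30))]
        predicted = [set(range(14)) | {100 + i for i in range(20)},
                     set(range(14)) | {200 + i for i in range(19)}]
        out = tagging_eval(gold, predicted)
        assert (out["n_matched"], out["n_predicted"], out["n_gold"]) == (28, 67, 61)
        assert out["precision"] == pytest.approx(28 / 67)
        assert out["recall"] == pytest.approx(28 / 61)
        assert round(out["precision"], 2) == 0.42
        assert round(out["recall"], 2) == 0.46

    def test_perfect_prediction(self):
        out = tagging_eval([{0, 1}, {2}], [{0, 1}, {2}])
        assert out["precision"] == out["recall"] == 1.0

    def test_empty_predictions_flag_undefined_precision(self):
        out = tagging_eval([{0}], [set()])
        assert out["precision"] is None and out["precision_undefined"]
        assert out["recall"] == 0.0

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            tagging_eval([{0}], [])
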