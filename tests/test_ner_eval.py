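"""Dual-level metric engine against independent oracles."""

import random

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from epiharvest.corpus import NO_ABRV_DIS, repair_iob2
from epiharvest.ner_eval import (
    EntitySpan,
    EvalLevel,
    entity_level_metrics,
    evaluate,
    extract_entities,
    f1,
    token_level_metrics,
)


class TestF1:
    @pytest.mark.parametrize(
        "p, r, expected",
        [
            (0.813, 0.821, 0.817),  # test-set overall entity level
            (0.824, 0.851, 0.837),  # validation overall entity level
            (0.921, 0.865, 0.892),  # validation overall token level
            (0.0, 0.0, 0.0),
        ],
    )
    def test_harmonic_mean(self, p, r, expected):
        assert f1(p, r) == pytest.approx(expected, abs=5e-4)


class TestExtractEntities:
    def test_four_token_rate_entity(self):
        spans = extract_entities(["B-STAT", "I-STAT", "I-STAT", "I-STAT"])
        assert spans == [EntitySpan("STAT", 0, 0, 4)]

    def test_all_outside(self):
        assert extract_entities(["O", "O"]) == []

    def test_adjacent_singletons(self):
        assert extract_entities(["B-LOC", "B-LOC"]) == [
            EntitySpan("LOC", 0, 0, 1),
            EntitySpan("LOC", 0, 1, 2),
        ]

    def test_dangling_inside_repaired_to_begin(self):
        assert extract_entities(["O", "I-LOC"]) == [EntitySpan("LOC", 0, 1, 2)]


class TestWorkedExample:
    gold = [["B-EPI", "I-EPI", "I-EPI"]]
    pred = [["B-EPI", "I-EPI", "O"]]

    def test_token_level_recall_two_thirds(self):
        report = token_level_metrics(self.gold, self.pred)
        assert report.per_class["EPI"].recall == pytest.approx(2 / 3)
        assert report.per_class["EPI"].precision == pytest.approx(1.0)

    def test_entity_level_marks_whole_entity_incorrect(self):
        report = entity_level_metrics(self.gold, self.pred)
        assert report.per_class["EPI"].recall == 0.0
        assert report.per_class["EPI"].precision == 0.0


def random_tags(rng, n_sentences, max_len, scheme=NO_ABRV_DIS):
    out = []
    for _ in range(n_sentences):
        length = rng.randint(1, max_len)
        out.append(repair_iob2([rng.choice(scheme.tags) for _ in range(length)]))
    return out


def oracle_entity_spans(tags, sentence_index):
    """Brute force: test every (start, end, class) triple directly."""
    spans = set()
    n = len(tags)
    for start in range(n):
        for end in range(start + 1, n + 1):
            for cls in {t[2:] for t in tags if t != "O"}:
                if (
                    tags[start] == f"B-{cls}"
                    and all(t == f"I-{cls}" for t in tags[start + 1 : end])
                    and (end == n or tags[end] != f"I-{cls}")
                ):
                    spans.add((cls, sentence_index, start, end))
    return spans


class TestAgainstOracles:
    def test_entity_metrics_equal_brute_force(self):
        rng = random.Random(42)
        gold = random_tags(rng, 200, 10)
        pred = random_tags(rng, 200, 10)
        pred = [p[: len(g)] + ["O"] * (len(g) - len(p)) for g, p in zip(gold, pred)]
        report = entity_level_metrics(gold, pred)

        g_spans, p_spans = set(), set()
        for i, (g, p) in enumerate(zip(gold, pred)):
            g_spans |= oracle_entity_spans(g, i)
            p_spans |= oracle_entity_spans(p, i)
        for cls, m in report.per_class.items():
            gc = {s for s in g_spans if s[0] == cls}
            pc = {s for s in p_spans if s[0] == cls}
            tp = len(gc & pc)
            assert m.precision == pytest.approx(tp / len(pc) if pc else 0.0)
            assert m.recall == pytest.approx(tp / len(gc) if gc else 0.0)
            assert m.support == len(gc)
        tp_all = len(g_spans & p_spans)
        assert report.overall.precision == pytest.approx(tp_all / len(p_spans))
        assert report.overall.recall == pytest.approx(tp_all / len(g_spans))

    def test_token_metrics_equal_sklearn(self):
        rng = random.Random(7)
        gold = random_tags(rng, 500, 12)
        pred = [
            [rng.choice(NO_ABRV_DIS.tags) if rng.random() < 0.3 else t for t in g]
            for g in gold
        ]
        report = token_level_metrics(gold, pred)
        y_true = [t[2:] if t != "O" else "O" for g in gold for t in g]
        y_pred = [t[2:] if t != "O" else "O" for p in pred for t in p]
        classes = sorted(report.per_class)
        p, r, f, support = precision_recall_fscore_support(
            y_true, y_pred, labels=classes, zero_division=0.0
        )
        for cls, pi, ri, fi, si in zip(classes, p, r, f, support):
            m = report.per_class[cls]
            assert m.precision == pytest.approx(pi)
            assert m.recall == pytest.approx(ri)
            assert m.f1 == pytest.approx(fi)
            assert m.support == si
        pm, rm, fm, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=classes, average="micro", zero_division=0.0
        )
        assert report.overall.precision == pytest.approx(pm)
        assert report.overall.recall == pytest.approx(rm)
        # accuracy compares full tags (prefix included)
        acc = np.mean(
            [t == q for g, pq in zip(gold, pred) for t, q in zip(g, pq)]
        )
        assert report.accuracy == pytest.approx(acc)


class TestInvariants:
    def test_perfect_prediction_scores_one_at_both_levels(self, small_synthetic):
        corpus, _ = small_synthetic
        reports = evaluate(corpus, corpus)
        for report in reports.values():
            assert report.overall.f1 == 1.0
        assert reports[EvalLevel.TOKEN].accuracy == 1.0

    def test_disjoint_prediction_scores_zero(self):
        gold = [["B-LOC", "I-LOC", "O"]]
        pred = [["O", "O", "B-SEX"]]
        for report in evaluate(gold, pred).values():
            assert report.overall.f1 == 0.0

    def test_swapping_gold_and_pred_swaps_precision_recall(self):
        rng = random.Random(5)
        gold = random_tags(rng, 50, 8)
        pred = random_tags(rng, 50, 8)
        pred = [p[: len(g)] + ["O"] * (len(g) - len(p)) for g, p in zip(gold, pred)]
        for fn in (entity_level_metrics, token_level_metrics):
            fwd, rev = fn(gold, pred), fn(pred, gold)
            assert fwd.overall.precision == pytest.approx(rev.overall.recall)
            assert fwd.overall.recall == pytest.approx(rev.overall.precision)

    def test_micro_average_equals_pooled_counts(self):
        rng = random.Random(11)
        gold = random_tags(rng, 80, 10)
        pred = random_tags(rng, 80, 10)
        pred = [p[: len(g)] + ["O"] * (len(g) - len(p)) for g, p in zip(gold, pred)]
        for fn in (entity_level_metrics, token_level_metrics):
            report = fn(gold, pred)
            tp = sum(c[0] for c in report.counts.values())
            fp = sum(c[1] for c in report.counts.values())
            fn_ = sum(c[2] for c in report.counts.values())
            assert report.overall.precision == pytest.approx(
                tp / (tp + fp) if tp + fp else 0.0
            )
            assert report.overall.recall == pytest.approx(
                tp / (tp + fn_) if tp + fn_ else 0.0
            )

    def test_alignment_error(self):
        with pytest.raises(ValueError, match="aligned"):
            entity_level_metrics([["O", "O"]], [["O"]])
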