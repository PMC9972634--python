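"""Distant/prescriptive/noisy channels, span merging and IOB2 emission."""

import itertools
import random

import pytest

from epiharvest.corpus import EntityClass, validate_iob2
from epiharvest.preprocess import clean_text, preprocess_abstract, tokenize
from epiharvest.weak_labeler import (
    Channel,
    Gazetteer,
    WeakLabelSpan,
    distant_label,
    emit_iob2,
    heuristic_ner_provider,
    label_abstract,
    merge_spans,
    noisy_label,
    prescriptive_label,
)


def toks(text):
    return tokenize(clean_text(text))


def surfaces(sentence, spans):
    texts = [t.text for t in sentence]
    return {(" ".join(texts[s.start : s.end]), s.cls.value) for s in spans}


class TestDistant:
    def test_disease_phrase(self, gazetteers):
        spans = distant_label(toks("Krabbe disease"), gazetteers)
        assert surfaces(toks("Krabbe disease"), spans) == {("Krabbe disease", "DIS")}

    def test_location_worked_example(self, gazetteers):
        sent = toks("the United States and Canada")
        spans = distant_label(sent, gazetteers)
        assert surfaces(sent, spans) == {
            ("the United States", "LOC"),
            ("Canada", "LOC"),
        }

    def test_no_hits(self, gazetteers):
        assert distant_label(toks("completely unrelated words"), gazetteers) == []

    def test_empty_gazetteer_set_rejected(self):
        with pytest.raises(ValueError):
            distant_label(toks("anything"), [])

    def test_longest_match_beats_shorter_cross_gazetteer(self, gazetteers):
        # "Czech Republic" (LOC) must win over the ethnonym "Czech"
        sent = toks("a study in the Czech Republic")
        assert surfaces(sent, distant_label(sent, gazetteers)) == {
            ("the Czech Republic", "LOC")
        }

    def test_all_caps_entries_match_case_sensitively(self):
        gaz = Gazetteer([("AFM", EntityClass.DIS), ("child", EntityClass.SEX)],
                        "test")
        assert distant_label(toks("AFM cohort"), [gaz])
        assert distant_label(toks("afm cohort"), [gaz]) == []
        # lowercase entries still match case-insensitively
        assert distant_label(toks("Child cohort"), [gaz])


class TestPrescriptive:
    @pytest.mark.parametrize(
        "text, expected",
        [
            (
                "a prevalence rate of RS of 1 in 40,760 in North Dakota",
                {("prevalence rate", "EPI"), ("1 in 40760", "STAT")},
            ),
            (
                "The prevalence of EE was calculated to be 17.1/100,000.",
                {("prevalence", "EPI"), ("17.1 / 100000", "STAT")},
            ),
            (
                "an estimated occurrence rate of 4.5%",
                {("estimated occurrence rate", "EPI"), ("4.5 %", "STAT")},
            ),
            ("incidence at birth was measured", {("incidence at birth", "EPI")}),
            ("screening identified 1:1800 newborns", {("1 : 1800", "STAT")}),
            ("a prevalence of 1.36 per million inhabitants",
             {("prevalence", "EPI"), ("1.36 per million inhabitants", "STAT")}),
            ("The study enrolled patients.", set()),
        ],
    )
    def test_worked_phrases(self, text, expected):
        sent = toks(text)
        assert surfaces(sent, prescriptive_label(sent)) == expected


class TestNoisy:
    def test_date_range_detected(self):
        sent = toks("in Finland between 1985 and 2006")
        spans = noisy_label(sent, heuristic_ner_provider)
        assert surfaces(sent, spans) == {("between 1985 and 2006", "DATE")}

    def test_unmapped_provider_type_discarded(self):
        sent = toks("the WHO registry")
        spans = noisy_label(sent, lambda s: [(1, 2, "ORG")])
        assert spans == []

    def test_provider_failure_is_skipped_with_warning(self):
        def boom(sentence):
            raise RuntimeError("model unavailable")

        with pytest.warns(UserWarning, match="noisy channel skipped"):
            assert noisy_label(toks("some text"), boom) == []

    def test_null_provider(self):
        assert noisy_label(toks("some text"), None) == []


class TestMergeSpans:
    def test_distant_loc_beats_noisy_ethn(self):
        loc = WeakLabelSpan(0, 0, 2, EntityClass.LOC, Channel.DISTANT)
        ethn = WeakLabelSpan(0, 0, 1, EntityClass.ETHN, Channel.NOISY)
        assert merge_spans([loc, ethn]) == [loc]

    def test_brute_force_resolution_on_conflicts(self):
        # every ordering and every subset conflict resolves to the same
        # winner predicted by (priority, length, leftmost)
        a = WeakLabelSpan(0, 0, 3, EntityClass.STAT, Channel.PRESCRIPTIVE)
        b = WeakLabelSpan(0, 2, 4, EntityClass.LOC, Channel.DISTANT)
        c = WeakLabelSpan(0, 3, 5, EntityClass.DATE, Channel.NOISY)
        for perm in itertools.permutations([a, b, c]):
            assert merge_spans(perm) == [a, c]

    def test_disjoint_unchanged(self):
        s1 = WeakLabelSpan(0, 0, 1, EntityClass.LOC, Channel.DISTANT)
        s2 = WeakLabelSpan(0, 2, 3, EntityClass.SEX, Channel.DISTANT)
        assert merge_spans([s2, s1]) == [s1, s2]

    def test_duplicates_collapse(self):
        s = WeakLabelSpan(0, 0, 2, EntityClass.LOC, Channel.DISTANT)
        assert merge_spans([s, s, s]) == [s]

    def test_permutation_invariance_random(self):
        rng = random.Random(3)
        classes = list(EntityClass)
        spans = []
        for _ in range(12):
            start = rng.randrange(0, 10)
            spans.append(
                WeakLabelSpan(
                    rng.randrange(2),
                    start,
                    start + rng.randint(1, 3),
                    rng.choice(classes),
                    rng.choice(list(Channel)),
                )
            )
        reference = merge_spans(spans)
        for _ in range(20):
            rng.shuffle(spans)
            assert merge_spans(spans) == reference


class TestEmit:
    def test_worked_example_with_the_in_span(self, gazetteers):
        sent = toks("the United States and Canada")
        tags = emit_iob2(sent, merge_spans(distant_label(sent, gazetteers)))
        assert tags == ["B-LOC", "I-LOC", "I-LOC", "O", "B-LOC"]

    def test_two_token_span_emission(self):
        sent = toks("the United States and Canada")
        spans = [
            WeakLabelSpan(0, 1, 3, EntityClass.LOC, Channel.DISTANT),
            WeakLabelSpan(0, 4, 5, EntityClass.LOC, Channel.DISTANT),
        ]
        assert emit_iob2(sent, spans) == ["O", "B-LOC", "I-LOC", "O", "B-LOC"]

    def test_no_spans_all_outside(self):
        assert emit_iob2(toks("a b c"), []) == ["O", "O", "O"]

    def test_span_at_sentence_end(self):
        sent = toks("reported in Finland")
        spans = [WeakLabelSpan(0, 2, 3, EntityClass.LOC, Channel.DISTANT)]
        assert emit_iob2(sent, spans) == ["O", "O", "B-LOC"]

    def test_overlap_rejected(self):
        sent = toks("a b c")
        spans = [
            WeakLabelSpan(0, 0, 2, EntityClass.LOC, Channel.DISTANT),
            WeakLabelSpan(0, 1, 3, EntityClass.SEX, Channel.DISTANT),
        ]
        with pytest.raises(ValueError, match="overlapping"):
            emit_iob2(sent, spans)


class TestLabelAbstract:
    def test_emits_valid_iob2_and_never_abrv(self, small_synthetic, gazetteers):
        _, batch = small_synthetic
        for g in batch[:5]:
            labeled = label_abstract(preprocess_abstract(g.raw), gazetteers)
            for sent in labeled.sentences:
                validate_iob2(sent.tags)
                assert not any(t.endswith("ABRV") for t in sent.tags)

    def test_channel_ablation_monotonicity(self, small_synthetic, gazetteers):
        # adding the noisy channel never evicts a higher-priority winner
        _, batch = small_synthetic
        for g in batch[:5]:
            tok = preprocess_abstract(g.raw)
            for idx, sentence in enumerate(tok.sentences):
                high = (
                    distant_label(sentence, gazetteers, idx)
                    + prescriptive_label(sentence, sentence_index=idx)
                )
                noisy = noisy_label(sentence, heuristic_ner_provider, idx)
                without = merge_spans(high)
                with_noisy = merge_spans(high + noisy)
                assert set(without) <= set(with_noisy)
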