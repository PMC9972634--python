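"""Corpus types, IOB2 round-trips, scheme conversion, counting, splitting."""

import io

import pytest
from hypothesis import given, strategies as st

from epiharvest.corpus import (
    Corpus,
    EntityClass,
    LabeledAbstract,
    LabeledSentence,
    LabelScheme,
    MERGED_ABRV_DIS,
    NO_ABRV_DIS,
    ParseError,
    STANDARD,
    SchemeError,
    Token,
    ValidationError,
    convert_scheme,
    label_counts,
    read_iob2,
    split_corpus,
    validate_iob2,
    write_iob2,
)
from epiharvest.fixtures import GenerationConfig, generate_corpus


def make_corpus(sentences, scheme=STANDARD, pmid="123"):
    return Corpus(
        "custom",
        [
            LabeledAbstract(
                pmid,
                [
                    LabeledSentence([Token(t) for t in toks], list(tags))
                    for toks, tags in sentences
                ],
            )
        ],
        scheme,
    )


class TestSchemes:
    def test_tag_inventory_is_2n_plus_1(self):
        for scheme, n in [(STANDARD, 8), (MERGED_ABRV_DIS, 7), (NO_ABRV_DIS, 6)]:
            assert len(scheme.tags) == 2 * n + 1
            assert scheme.tags[0] == "O"

    def test_no_abrv_dis_excludes_disease_classes(self):
        names = {c.value for c in NO_ABRV_DIS.classes}
        assert names == {"EPI", "STAT", "LOC", "DATE", "SEX", "ETHN"}


class TestReadIob2:
    def test_epi_phrase_file(self):
        text = "-DOCSTART- 1\nincidence B-EPI\nat I-EPI\nbirth I-EPI\n"
        corpus = read_iob2(io.StringIO(text), STANDARD)
        (abstract,) = corpus.abstracts
        (sent,) = abstract.sentences
        assert sent.texts() == ["incidence", "at", "birth"]
        assert sent.tags == ["B-EPI", "I-EPI", "I-EPI"]

    def test_empty_stream(self):
        assert len(read_iob2(io.StringIO(""), STANDARD)) == 0

    def test_dangling_inside_tag_is_rejected(self):
        with pytest.raises(ValidationError, match="sentence 0"):
            read_iob2(io.StringIO("-DOCSTART- 1\nFinland I-LOC\n"), STANDARD)

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(ParseError, match="line 3"):
            read_iob2(
                io.StringIO("-DOCSTART- 1\na O\nb O extra\n"), STANDARD
            )

    def test_tag_outside_scheme(self):
        with pytest.raises(SchemeError):
            read_iob2(io.StringIO("-DOCSTART- 1\nx B-DIS\n"), NO_ABRV_DIS)


@pytest.mark.parametrize("seed", [0, 7, 99])
def test_roundtrip_on_generated_corpora(seed):
    corpus, _ = generate_corpus(GenerationConfig(n_abstracts=5, seed=seed))
    text = write_iob2(corpus)
    again = read_iob2(io.StringIO(text), STANDARD, name=corpus.name)
    assert again == corpus
    assert write_iob2(again) == text


class TestConvertScheme:
    def test_merge_relabels_abrv_as_dis(self):
        c = make_corpus([(["KD", "disease"], ["B-ABRV", "I-ABRV"])])
        out = convert_scheme(c, MERGED_ABRV_DIS)
        assert next(out.sentences()).tags == ["B-DIS", "I-DIS"]

    def test_merge_preserves_entity_boundary_after_dis(self):
        # a former B-ABRV directly after a DIS span must stay a B- boundary
        c = make_corpus(
            [(["Krabbe", "disease", "KD"], ["B-DIS", "I-DIS", "B-ABRV"])]
        )
        out = convert_scheme(c, MERGED_ABRV_DIS)
        assert next(out.sentences()).tags == ["B-DIS", "I-DIS", "B-DIS"]

    def test_drop_classes_to_null_label(self):
        c = make_corpus([(["Krabbe", "disease"], ["B-DIS", "I-DIS"])])
        out = convert_scheme(c, NO_ABRV_DIS)
        assert next(out.sentences()).tags == ["O", "O"]

    def test_identity_conversion(self, small_synthetic):
        corpus, _ = small_synthetic
        assert convert_scheme(corpus, STANDARD) == corpus

    def test_missing_class_raises(self):
        c = make_corpus([(["x"], ["O"])], scheme=NO_ABRV_DIS)
        with pytest.raises(SchemeError):
            convert_scheme(c, STANDARD)

    @pytest.mark.parametrize("target", [MERGED_ABRV_DIS, NO_ABRV_DIS])
    def test_never_increases_label_mass(self, small_synthetic, target):
        corpus, _ = small_synthetic
        out = convert_scheme(corpus, target)

        def non_o(c):
            return sum(t != "O" for s in c.sentences() for t in s.tags)

        if target is MERGED_ABRV_DIS:
            assert non_o(out) == non_o(corpus)
        else:
            assert non_o(out) <= non_o(corpus)


class TestLabelCounts:
    def test_all_o_corpus(self):
        c = make_corpus([(["a", "b"], ["O", "O"])])
        df = label_counts(c)
        assert df.loc["ALL", "count"] == 0
        assert (df["count"][:-1] == 0).all()

    def test_percentages_sum_to_100(self, small_synthetic):
        corpus, _ = small_synthetic
        df = label_counts(corpus)
        assert abs(df["pct_of_labels"][:-1].sum() - 100.0) <= 0.05

    def test_counts_match_tags(self):
        c = make_corpus(
            [(["a", "b", "c"], ["B-LOC", "I-LOC", "O"])]
        )
        df = label_counts(c)
        assert df.loc["LOC", "count"] == 2
        assert df.loc["ALL", "pct_of_labels"] == pytest.approx(66.67)


class TestSplitCorpus:
    @staticmethod
    def corpus_of(n):
        return Corpus(
            "c",
            [LabeledAbstract(str(i), [LabeledSentence([Token("x")], ["O"])])
             for i in range(n)],
            STANDARD,
        )

    def test_sizes_small(self):
        train, val, test = split_corpus(self.corpus_of(10), test_n=2,
                                        val_ratio=0.25, seed=1)
        assert (len(train), len(val), len(test)) == (6, 2, 2)

    def test_sizes_at_reference_scale(self):
        train, val, test = split_corpus(self.corpus_of(609), seed=42)
        assert len(test) == 50
        assert len(train) + len(val) + len(test) == 609

    def test_deterministic_and_exhaustive(self):
        c = self.corpus_of(25)
        a = split_corpus(c, test_n=5, val_ratio=0.2, seed=9)
        b = split_corpus(c, test_n=5, val_ratio=0.2, seed=9)
        ids = lambda parts: [sorted(x.pmid for x in p.abstracts) for p in parts]
        assert ids(a) == ids(b)
        union = {x.pmid for p in a for x in p.abstracts}
        assert union == {str(i) for i in range(25)}
        assert sum(len(p) for p in a) == 25

    def test_test_n_too_large(self):
        with pytest.raises(ValueError):
            split_corpus(self.corpus_of(5), test_n=5)


@given(st.lists(st.sampled_from(sorted(STANDARD.tags)), max_size=12))
def test_validate_accepts_exactly_wellformed_sequences(tags):
    prev = "O"
    ok = True
    for t in tags:
        if t.startswith("I-") and prev not in (f"B-{t[2:]}", f"I-{t[2:]}"):
            ok = False
        prev = t
    if ok:
        validate_iob2(tags, STANDARD)
    else:
        with pytest.raises(ValidationError):
            validate_iob2(tags, STANDARD)
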