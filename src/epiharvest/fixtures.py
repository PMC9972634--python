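"""Synthetic rare-disease epidemiology abstracts with gold annotations.

The generator emulates the statistical structure of a weakly-labeled
epidemiology corpus: per-class token proportions default to the validated
training-set composition (diseases dominate, followed by abbreviations,
then rates/types/locations/dates/sex/ethnonyms), rates are planted in the
canonical surface forms the prescriptive rules cover (X in Y, X/Y,
X per Y, percent, per-million), and a configurable fraction of rates is
emitted in a truncated, denominator-ellipted form that the rules are
expected to miss.

Templates deliberately stay inside the rule grammar, so the weak labeler's
recall on canonical-form synthetic text is an exact 1.0 oracle (over the
seven auto-labeled classes; ABRV is planted in gold but is a manual-only
class the labeler never emits). A small set of hand-encoded worked-example
fixtures with gold spans is bundled for regression tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .corpus import (
    Corpus,
    LabeledAbstract,
    LabeledSentence,
    STANDARD,
    Token,
    validate_iob2,
)
from .preprocess import RawAbstract
from .weak_labeler import _read_data

__all__ = [
    "GenerationConfig",
    "GoldAbstract",
    "Fixture",
    "generate_abstract",
    "generate_corpus",
    "inpaper_fixtures",
    "gracile_abstract",
    "case_study_dictionary_lines",
    "case_fixture_abstracts",
]

#: Training-set per-class share of labeled (non-O) tokens.
DEFAULT_CLASS_MIX = {
    "DIS": 0.4896,
    "ABRV": 0.1753,
    "DATE": 0.0640,
    "LOC": 0.0741,
    "EPI": 0.0724,
    "ETHN": 0.0186,
    "SEX": 0.0273,
    "STAT": 0.0787,
}

DEFAULT_RATE_FORM_MIX = {
    "x_in_y": 0.30,
    "slash": 0.20,
    "x_per_y": 0.20,
    "percent": 0.15,
    "per_million": 0.15,
}


@dataclass
class GenerationConfig:
    n_abstracts: int = 50
    seed: int = 42
    class_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    rate_form_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RATE_FORM_MIX)
    )
    incomplete_rate_fraction: float = 0.1
    min_sentences: int = 3
    max_sentences: int = 6

    def __post_init__(self):
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 0.01:
            raise ValueError(f"class_mix sums to {total:.3f}, expected 1")


@dataclass
class GoldAbstract:
    raw: RawAbstract
    gold: LabeledAbstract
    planted: dict[str, list[str]]
    expected_misses: list[tuple[int, str]]  # (sentence index, surface)


# ---------------------------------------------------------------------------
# lexical pools (from the bundled gazetteers, so labeler and generator agree)
# ---------------------------------------------------------------------------

def _surfaces(filename: str) -> list[str]:
    out = []
    for line in _read_data(filename).splitlines():
        if line.strip() and not line.startswith("#"):
            out.append(line.split("\t")[0])
    return out


def _dedup_the(surfaces: list[str]) -> list[str]:
    """Drop bare forms whose the-prefixed twin is also present, so a planted
    surface is always the longest gazetteer match."""
    lowered = {s.casefold() for s in surfaces}
    return [s for s in surfaces if f"the {s.casefold()}" not in lowered]


_DISEASES = _surfaces("diseases.tsv")
_LOCATIONS = _dedup_the(_surfaces("locations.tsv"))
_ETHNONYMS = _surfaces("ethnonyms.tsv")
_SEX_TERMS = _surfaces("sex_terms.tsv")

_EPI_PHRASES = [
    ["prevalence"],
    ["incidence"],
    ["point", "prevalence"],
    ["birth", "prevalence"],
    ["annual", "incidence"],
    ["estimated", "occurrence", "rate"],
    ["prevalence", "rate"],
    ["incidence", "rate"],
    ["pooled", "frequency"],
    ["incidence", "at", "birth"],
]

# denominators avoid the 1500-2100 band so they can never look like years
_DENOMINATORS = [4698, 5263, 10000, 18000, 25000, 40760, 47000, 50000,
                 100000, 250000, 311000]
_DEC_NUMERATORS = ["0.64", "1.36", "2.8", "6.002", "17.1", "30.4", "95.1"]
_POP_NOUNS = ["births", "inhabitants", "newborns", "people", "persons",
              "population"]

_FILLERS = [
    "The authors reviewed hospital records and compared them with published reports .",
    "Diagnostic confirmation relied on genetic testing at a referral centre .",
    "Ascertainment was considered complete for the catchment area .",
    "The clinical course and laboratory findings are also described .",
]

_INTRO = "We conducted a population based epidemiologic surveillance survey ."

_NO_SPACE_BEFORE = {".", ",", ")", "%", ":", ";", "/"}
_NO_SPACE_AFTER = {"(", "/"}


def _detokenize(texts: list[str]) -> tuple[str, list[Token]]:
    """Join tokens into sentence text with character offsets per token."""
    out: list[str] = []
    tokens: list[Token] = []
    pos = 0
    prev = ""
    for text in texts:
        if out and text not in _NO_SPACE_BEFORE and prev not in _NO_SPACE_AFTER:
            out.append(" ")
            pos += 1
        out.append(text)
        tokens.append(Token(text, pos, pos + len(text)))
        pos += len(text)
        prev = text
    return "".join(out), tokens


def _abbrev(name: str) -> str:
    letters = [w[0] for w in name.replace("-", " ").split() if w[0].isalpha()]
    return "".join(letters).upper() if len(letters) > 1 else (name[:2].upper() + "X")


def _realize_rate(rng: random.Random, form: str) -> list[str]:
    if form == "x_in_y":
        return ["1", "in", str(rng.choice(_DENOMINATORS))]
    if form == "slash":
        return ["1", "/", str(rng.choice(_DENOMINATORS))]
    if form == "x_per_y":
        toks = [rng.choice(_DEC_NUMERATORS), "per", str(rng.choice(_DENOMINATORS))]
        if rng.random() < 0.5:
            toks.append(rng.choice(_POP_NOUNS))
        return toks
    if form == "percent":
        return [rng.choice(["0.5", "1.2", "4.5", "12.0"]), "%"]
    if form == "per_million":
        toks = [rng.choice(_DEC_NUMERATORS), "per", "million"]
        if rng.random() < 0.5:
            toks.append(rng.choice(_POP_NOUNS))
        return toks
    raise ValueError(f"unknown rate form {form!r}")


def _realize_date(rng: random.Random) -> tuple[list[str], int, int]:
    """Returns (tokens, gold_start, gold_end) — prepositions introducing a
    bare year stay outside the gold span."""
    y1 = rng.randint(1960, 2015)
    y2 = y1 + rng.randint(1, 8)
    kind = rng.randrange(4)
    if kind == 0:
        toks = ["between", str(y1), "and", str(y2)]
        return toks, 0, 4
    if kind == 1:
        toks = ["from", str(y1), "to", str(y2)]
        return toks, 0, 4
    if kind == 2:
        toks = ["in", str(y1)]
        return toks, 1, 2
    month = rng.choice(["January", "March", "June", "October", "December"])
    toks = ["in", month, str(y1)]
    return toks, 1, 3


def _weighted_choice(rng: random.Random, weights: dict[str, float]) -> str:
    items = sorted(weights.items())
    r = rng.random() * sum(w for _, w in items)
    acc = 0.0
    for key, w in items:
        acc += w
        if r <= acc:
            return key
    return items[-1][0]


def _pick_classes(
    counts: dict[str, int], mix: dict[str, float], k: int
) -> list[str]:
    active = [c for c, w in mix.items() if w > 0]
    total = sum(counts.values())
    deficits = {
        c: mix[c] - (counts[c] / total if total else 0.0) for c in active
    }
    ranked = sorted(active, key=lambda c: (-deficits[c], c))
    return ranked[: min(k, len(ranked))]


def _build_sentence(
    rng: random.Random,
    classes: list[str],
    config: GenerationConfig,
) -> tuple[list[str], list[str], list[tuple[str, str]], str | None]:
    """Assemble one sentence; returns (token texts, tags, planted
    (class, surface) pairs, expected-miss surface or None)."""
    texts: list[str] = []
    tags: list[str] = []
    planted: list[tuple[str, str]] = []
    miss: str | None = None

    def add(tokens: list[str], cls: str | None,
            gold: tuple[int, int] | None = None) -> None:
        start = len(texts)
        texts.extend(tokens)
        if cls is None:
            tags.extend(["O"] * len(tokens))
            return
        g0, g1 = gold if gold else (0, len(tokens))
        for i in range(len(tokens)):
            if g0 <= i < g1:
                tags.append(f"B-{cls}" if i == g0 else f"I-{cls}")
            else:
                tags.append("O")
        planted.append((cls, " ".join(tokens[g0:g1])))

    have = set(classes)
    add(["The"], None)
    if "EPI" in have:
        add(list(rng.choice(_EPI_PHRASES)), "EPI")
    else:
        add(["study"], None)
    if "DIS" in have:
        add(["of"], None)
        disease = rng.choice(_DISEASES)
        dis_tokens = disease.replace("-", " - ").split()
        add(dis_tokens, "DIS")
        if "ABRV" in have:
            add(["("], None)
            add([_abbrev(disease)], "ABRV")
            add([")"], None)
    elif "ABRV" in have:
        add(["of", "the"], None)
        add([_abbrev(rng.choice(_DISEASES))], "ABRV")
        add(["cohort"], None)
    if "LOC" in have:
        add(["in"], None)
        add(rng.choice(_LOCATIONS).split(), "LOC")
    if "ETHN" in have or "SEX" in have:
        add(["among"], None)
        if "ETHN" in have:
            add(rng.choice(_ETHNONYMS).split(), "ETHN")
        if "SEX" in have:
            add([rng.choice(_SEX_TERMS)], "SEX")
        else:
            add(["residents"], None)
    add(["was"], None)
    if "STAT" in have:
        if rng.random() < config.incomplete_rate_fraction:
            numerator = rng.choice(_DEC_NUMERATORS)
            start = len(texts)
            texts.append(numerator)
            tags.append("B-STAT")
            miss = numerator
            planted.append(("STAT", numerator))
        else:
            form = _weighted_choice(rng, config.rate_form_mix)
            add(_realize_rate(rng, form), "STAT")
    else:
        add(["assessed"], None)
    if "DATE" in have:
        toks, g0, g1 = _realize_date(rng)
        add(toks, "DATE", (g0, g1))
    add(["."], None)
    return texts, tags, planted, miss


def generate_abstract(config: GenerationConfig, index: int,
                      _counts: dict[str, int] | None = None) -> GoldAbstract:
    """Generate one abstract deterministically from (config.seed, index)."""
    rng = random.Random((config.seed * 1_000_003 + index) % 2**31)
    counts = _counts if _counts is not None else {c: 0 for c in DEFAULT_CLASS_MIX}
    n_entity_sents = rng.randint(config.min_sentences, config.max_sentences)

    sentence_texts: list[str] = [_INTRO.replace(" .", ".")]
    gold_sentences: list[LabeledSentence] = []
    planted: dict[str, list[str]] = {c: [] for c in DEFAULT_CLASS_MIX}
    misses: list[tuple[int, str]] = []

    intro_tokens = _INTRO.split()
    text, toks = _detokenize(intro_tokens)
    sentence_texts[0] = text
    gold_sentences.append(LabeledSentence(toks, ["O"] * len(toks)))

    for _ in range(n_entity_sents):
        k = rng.randint(2, 4)
        classes = _pick_classes(counts, config.class_mix, k)
        texts, tags, pairs, miss = _build_sentence(rng, classes, config)
        text, tokens = _detokenize(texts)
        sentence_texts.append(text)
        gold_sentences.append(LabeledSentence(tokens, tags))
        for cls, surface in pairs:
            planted[cls].append(surface)
        for cls_tag in tags:
            if cls_tag != "O":
                counts[cls_tag[2:]] += 1
        if miss is not None:
            misses.append((len(gold_sentences) - 1, miss))
        if rng.random() < 0.4:
            filler = rng.choice(_FILLERS)
            text, tokens = _detokenize(filler.split())
            sentence_texts.append(text)
            gold_sentences.append(LabeledSentence(tokens, ["O"] * len(tokens)))

    pmid = f"SYN{index:06d}"
    raw = RawAbstract(pmid=pmid, title="", body=" ".join(sentence_texts))
    gold = LabeledAbstract(pmid=pmid, sentences=gold_sentences)
    for s in gold.sentences:
        validate_iob2(s.tags, STANDARD)
    return GoldAbstract(raw=raw, gold=gold, planted=planted,
                        expected_misses=misses)


def generate_corpus(config: GenerationConfig) -> tuple[Corpus, list[GoldAbstract]]:
    """A batch of abstracts plus the gold corpus over the 8-class scheme."""
    counts = {c: 0 for c in DEFAULT_CLASS_MIX}
    batch = [
        generate_abstract(config, i, _counts=counts)
        for i in range(config.n_abstracts)
    ]
    corpus = Corpus("synthetic", [g.gold for g in batch], STANDARD)
    return corpus, batch


# ---------------------------------------------------------------------------
# worked-example fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fixture:
    """A key phrase with hand-encoded gold annotation.

    Either token-level gold (``tokens``/``tags``) or expected entity
    surfaces per class (compared after stripping digit-group commas, which
    preprocessing removes).
    """

    name: str
    text: str
    tokens: tuple[str, ...] = ()
    tags: tuple[str, ...] = ()
    expected_surfaces: dict[str, tuple[str, ...]] = field(default_factory=dict)


def inpaper_fixtures() -> dict[str, Fixture]:
    fixtures = [
        Fixture(
            name="incidence_at_birth",
            text="incidence at birth",
            tokens=("incidence", "at", "birth"),
            tags=("B-EPI", "I-EPI", "I-EPI"),
        ),
        Fixture(
            name="united_states_canada",
            text="the United States and Canada",
            tokens=("the", "United", "States", "and", "Canada"),
            tags=("B-LOC", "I-LOC", "I-LOC", "O", "B-LOC"),
        ),
        Fixture(
            name="rett_key_phrase",
            text=(
                "Five patients with definite RS were identified in a "
                "population of 203,801 children (98,932 girls) 0-18 years "
                "of age yielding a prevalence rate of RS of 1 in 40,760 in "
                "North Dakota children."
            ),
            expected_surfaces={
                "EPI": ("prevalence rate",),
                "STAT": ("1 in 40,760",),
                "LOC": ("North Dakota",),
                "SEX": ("girls",),
            },
        ),
        Fixture(
            name="ee_key_phrase",
            text="The prevalence of EE was calculated to be 17.1/100,000.",
            expected_surfaces={
                "EPI": ("prevalence",),
                "STAT": ("17.1/100,000",),
            },
        ),
        Fixture(
            name="sms_key_phrase",
            text="Smith-Magenis syndrome (SMS) is rare (prevalence 1 in 25 000).",
            expected_surfaces={
                "EPI": ("prevalence",),
                "STAT": ("1 in 25 000",),
            },
        ),
        Fixture(
            name="fop_key_phrase",
            text=(
                "89 FOP patients were identified, which results in a "
                "prevalence of 1.36 per million inhabitants."
            ),
            expected_surfaces={
                "EPI": ("prevalence",),
                "STAT": ("1.36 per million inhabitants",),
            },
        ),
        Fixture(
            name="gpa_key_phrase",
            text=(
                "The annual incidence per million population increased "
                "from 5.2 to 12.0 in Northern Norway."
            ),
            expected_surfaces={
                "EPI": ("annual incidence",),
                "LOC": ("Northern Norway",),
            },
        ),
        Fixture(
            name="krabbe_discussion",
            text=(
                "Krabbe disease was the most common followed by Gaucher "
                "disease, metachromatic leukodystrophy and Salla disease."
            ),
            expected_surfaces={
                "DIS": (
                    "Krabbe disease",
                    "Gaucher disease",
                    "metachromatic leukodystrophy",
                    "Salla disease",
                ),
            },
        ),
        Fixture(
            name="smith_magenis_no_loc",
            text="Smith-Magenis syndrome (SMS) is rare (prevalence 1 in 25 000).",
            expected_surfaces={"LOC": ()},
        ),
    ]
    return {f.name: f for f in fixtures}


def gracile_abstract() -> RawAbstract:
    """Synthetic stand-in abstract echoing the GRACILE-syndrome worked
    extraction (incidence at least 1/47,000 in Finland, Finnish founder
    population)."""
    return RawAbstract(
        pmid="FIX47000",
        title="The GRACILE syndrome, a neonatal lethal metabolic disorder with iron overload.",
        body=(
            "GRACILE syndrome is a uniformly fatal neonatal disorder. "
            "We reviewed epidemiologic surveillance data for this syndrome. "
            "Incidence of the syndrome in Finland is at least 1/47,000, "
            "consistent with enrichment of the founder mutation in the "
            "Finnish population."
        ),
    )


def case_study_dictionary_lines() -> list[str]:
    """A disease dictionary (TSV lines) for the three worked case studies."""
    return [
        "GARD:0006667\tclassic homocystinuria\t"
        "homocystinuria due to cystathionine beta-synthase deficiency|"
        "cystathionine beta-synthase deficiency|"
        "homocystinuria due to cbs deficiency|cbs deficiency",
        "GARD:0000001\tGRACILE syndrome\t"
        "finnish lactic acidosis with hepatic hemosiderosis|"
        "finnish lethal neonatal metabolic syndrome|"
        "fellman syndrome|fellman disease",
        "GARD:0007383\tphenylketonuria\t"
        "phenylalanine hydroxylase deficiency|oligophrenia phenylpyruvica|"
        "folling disease",
    ]


def case_fixture_abstracts() -> list[RawAbstract]:
    """A tiny in-memory abstract store: one epidemiologic-study abstract
    (the GRACILE stand-in), one non-epidemiologic abstract of the same
    disease, and one unrelated abstract."""
    return [
        gracile_abstract(),
        RawAbstract(
            pmid="FIX00002",
            title="BCS1L mutations in GRACILE syndrome.",
            body=(
                "GRACILE syndrome is caused by mutations in BCS1L. "
                "We describe the molecular consequences of the founder allele."
            ),
        ),
        RawAbstract(
            pmid="FIX00003",
            title="Dietary management of classic homocystinuria.",
            body=(
                "We summarise protein-restricted diets for classic "
                "homocystinuria and monitoring of treatment adherence."
            ),
        ),
    ]
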