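"""Weakly-supervised IOB2 labeling: distant, prescriptive and noisy channels.

Three supervision channels propose candidate entity spans over a repaired
token sequence:

* **distant** — longest-match dictionary lookup against gazetteers
  (diseases → DIS, locations → LOC, ethnonyms → ETHN, sex terms → SEX);
* **prescriptive** — declarative token-pattern rules for epidemiologic
  type phrases (EPI) and rate expressions (STAT);
* **noisy** — a pluggable general-domain NER provider whose geopolitical,
  date and nationality types are mapped onto LOC, DATE and ETHN.

Channel outputs are merged into a non-overlapping span set (prescriptive >
distant > noisy, then longer, then leftmost) and emitted as IOB2 tags.
ABRV is deliberately never produced by any channel: disease abbreviations
are a manual-annotation class.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from importlib import resources
from typing import Callable, Iterable, Sequence

from .corpus import EntityClass, LabeledAbstract, LabeledSentence, Token, validate_iob2
from .preprocess import TokenizedAbstract, tokenize

__all__ = [
    "Channel",
    "Gazetteer",
    "RulePattern",
    "WeakLabelSpan",
    "load_gazetteer",
    "bundled_gazetteers",
    "load_rules",
    "bundled_rules",
    "heuristic_ner_provider",
    "distant_label",
    "prescriptive_label",
    "noisy_label",
    "merge_spans",
    "emit_iob2",
    "label_abstract",
]

NERProvider = Callable[[Sequence[Token]], list[tuple[int, int, str]]]


class Channel(IntEnum):
    """Supervision channels, ordered by merge priority (higher wins)."""

    NOISY = 1
    DISTANT = 2
    PRESCRIPTIVE = 3


@dataclass(frozen=True)
class WeakLabelSpan:
    """A candidate entity span over token indices (half-open)."""

    sentence_index: int
    start: int
    end: int
    cls: EntityClass
    source: Channel

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("span must satisfy start < end")

    @property
    def priority(self) -> int:
        return int(self.source)


class Gazetteer:
    """Case-folded surface-form dictionary mapping phrases to one class.

    Single-token ALL-CAPS entries (abbreviation-like, e.g. "ChILD"-type
    collisions) match case-sensitively; everything else case-insensitively.
    """

    def __init__(self, pairs: Iterable[tuple[str, EntityClass]], provenance: str):
        self.provenance = provenance
        self.phrases: dict[tuple[str, ...], EntityClass] = {}
        self.exact_phrases: dict[tuple[str, ...], EntityClass] = {}
        self.max_len = 0
        for surface, cls in pairs:
            if not surface.strip():
                raise ValueError(f"{provenance}: empty surface form")
            toks = tuple(t.text for t in tokenize(surface))
            if len(toks) == 1 and toks[0].isalpha() and toks[0].isupper():
                self.exact_phrases[toks] = cls
            else:
                self.phrases[tuple(t.casefold() for t in toks)] = cls
            self.max_len = max(self.max_len, len(toks))

    def lookup(self, window: Sequence[str]) -> EntityClass | None:
        exact = self.exact_phrases.get(tuple(window))
        if exact is not None:
            return exact
        return self.phrases.get(tuple(w.casefold() for w in window))

    def __len__(self) -> int:
        return len(self.phrases) + len(self.exact_phrases)


def load_gazetteer(lines: Iterable[str], provenance: str) -> Gazetteer:
    """Read a two-column TSV (surface form, class) gazetteer."""
    pairs = []
    for raw in lines:
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        surface, cls = line.split("\t")
        pairs.append((surface, EntityClass(cls)))
    return Gazetteer(pairs, provenance)


def _read_data(name: str) -> str:
    return resources.files("epiharvest.data").joinpath(name).read_text("utf-8")


def bundled_gazetteers(include_diseases: bool = True) -> list[Gazetteer]:
    """The mini-gazetteers shipped with the package (no download needed)."""
    names = ["locations.tsv", "ethnonyms.tsv", "sex_terms.tsv"]
    if include_diseases:
        names.insert(0, "diseases.tsv")
    return [
        load_gazetteer(_read_data(n).splitlines(), n.removesuffix(".tsv"))
        for n in names
    ]


# ---------------------------------------------------------------------------
# prescriptive channel: declarative token patterns
# ---------------------------------------------------------------------------

_NUM_RE = re.compile(r"\d+(?:\.\d+)?$")


@dataclass(frozen=True)
class _Element:
    alternatives: tuple[str, ...]  # casefolded literals; ("NUM",) is numeric
    quantifier: str = ""  # "", "?" or "*"

    def matches(self, token_text: str) -> bool:
        if self.alternatives == ("NUM",):
            return bool(_NUM_RE.fullmatch(token_text))
        return token_text.casefold() in self.alternatives


@dataclass(frozen=True)
class RulePattern:
    """One token-sequence rule: id, target class, compiled elements."""

    pattern_id: str
    cls: EntityClass
    elements: tuple[_Element, ...]
    source: str = ""

    def match_at(self, texts: Sequence[str], pos: int) -> int | None:
        """Longest end index of a full match starting at ``pos``, or None."""
        return _match(self.elements, 0, texts, pos)


def _match(elements: tuple[_Element, ...], ei: int,
           texts: Sequence[str], pos: int) -> int | None:
    if ei == len(elements):
        return pos
    el = elements[ei]
    best: int | None = None

    def consider(end: int | None) -> None:
        nonlocal best
        if end is not None and (best is None or end > best):
            best = end

    if el.quantifier == "*":
        # try the longest repetition first, then shorter, then zero
        reps = []
        p = pos
        while p < len(texts) and el.matches(texts[p]):
            p += 1
            reps.append(p)
        for end in reversed(reps):
            consider(_match(elements, ei + 1, texts, end))
        consider(_match(elements, ei + 1, texts, pos))
    else:
        if pos < len(texts) and el.matches(texts[pos]):
            consider(_match(elements, ei + 1, texts, pos + 1))
        if el.quantifier == "?":
            consider(_match(elements, ei + 1, texts, pos))
    return best


def _compile_element(spec: str) -> _Element:
    quantifier = ""
    if spec.endswith(("?", "*")):
        spec, quantifier = spec[:-1], spec[-1]
    if spec.startswith("(") and spec.endswith(")"):
        spec = spec[1:-1]
    if spec == "NUM":
        return _Element(("NUM",), quantifier)
    return _Element(tuple(a.casefold() for a in spec.split("|")), quantifier)


def parse_rule_line(line: str) -> RulePattern:
    pattern_id, cls, pattern = line.split("\t")
    return RulePattern(
        pattern_id,
        EntityClass(cls),
        tuple(_compile_element(p) for p in pattern.split()),
        source=pattern,
    )


def load_rules(lines: Iterable[str]) -> list[RulePattern]:
    """Read the declarative rule config: ``id<TAB>class<TAB>pattern`` lines,
    where a pattern is space-separated elements — NUM, a literal, or an
    ``(a|b)`` alternation, optionally suffixed ``?`` or ``*``."""
    out = []
    for raw in lines:
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        out.append(parse_rule_line(line))
    return out


_BUNDLED_RULES: list[RulePattern] | None = None


def bundled_rules() -> list[RulePattern]:
    global _BUNDLED_RULES
    if _BUNDLED_RULES is None:
        _BUNDLED_RULES = load_rules(_read_data("rules.cfg").splitlines())
    return _BUNDLED_RULES


# ---------------------------------------------------------------------------
# channels
# ---------------------------------------------------------------------------

def distant_label(
    sentence: Sequence[Token],
    gazetteers: Sequence[Gazetteer],
    sentence_index: int = 0,
) -> list[WeakLabelSpan]:
    """Longest-match, left-to-right gazetteer lookup over the sentence."""
    if not gazetteers:
        raise ValueError("at least one gazetteer is required")
    texts = [t.text for t in sentence]
    max_len = max(g.max_len for g in gazetteers)
    spans: list[WeakLabelSpan] = []
    i = 0
    while i < len(texts):
        hit: tuple[int, EntityClass] | None = None
        for length in range(min(max_len, len(texts) - i), 0, -1):
            window = texts[i : i + length]
            for gaz in gazetteers:
                cls = gaz.lookup(window)
                if cls is not None:
                    hit = (length, cls)
                    break
            if hit:
                break
        if hit:
            length, cls = hit
            spans.append(
                WeakLabelSpan(sentence_index, i, i + length, cls, Channel.DISTANT)
            )
            i += length
        else:
            i += 1
    return spans


def prescriptive_label(
    sentence: Sequence[Token],
    rules: Sequence[RulePattern] | None = None,
    sentence_index: int = 0,
) -> list[WeakLabelSpan]:
    """Apply the EPI/STAT token-pattern rules, longest match first."""
    if rules is None:
        rules = bundled_rules()
    texts = [t.text for t in sentence]
    spans: list[WeakLabelSpan] = []
    i = 0
    while i < len(texts):
        best: tuple[int, EntityClass] | None = None
        for rule in rules:
            end = rule.match_at(texts, i)
            if end is not None and end > i and (best is None or end > best[0]):
                best = (end, rule.cls)
        if best:
            end, cls = best
            spans.append(
                WeakLabelSpan(sentence_index, i, end, cls, Channel.PRESCRIPTIVE)
            )
            i = end
        else:
            i += 1
    return spans


_PROVIDER_TYPE_MAP = {
    "GPE": EntityClass.LOC,
    "LOC": EntityClass.LOC,
    "LOCATION": EntityClass.LOC,
    "FAC": EntityClass.LOC,
    "DATE": EntityClass.DATE,
    "NORP": EntityClass.ETHN,
}


def noisy_label(
    sentence: Sequence[Token],
    provider: NERProvider | None,
    sentence_index: int = 0,
) -> list[WeakLabelSpan]:
    """Map a general-domain NER provider's output onto LOC/DATE/ETHN;
    unmapped provider types are discarded, a failing provider is skipped."""
    if provider is None:
        return []
    try:
        raw = provider(sentence)
    except Exception as exc:  # channel failure must not kill the others
        warnings.warn(f"noisy channel skipped: {exc}", stacklevel=2)
        return []
    spans = []
    for start, end, kind in raw:
        cls = _PROVIDER_TYPE_MAP.get(kind.upper())
        if cls is not None:
            spans.append(WeakLabelSpan(sentence_index, start, end, cls, Channel.NOISY))
    return spans


_MONTHS = {
    "january", "february", "march", "april", "may", "june", "july",
    "august", "september", "october", "november", "december",
}


def _is_year(text: str) -> bool:
    return bool(re.fullmatch(r"\d{4}", text)) and 1500 <= int(text) <= 2100


def heuristic_ner_provider(sentence: Sequence[Token]) -> list[tuple[int, int, str]]:
    """Bundled rule-based stand-in for a general-domain NER model.

    Detects date expressions only: "between 1985 and 2006", "from 1994 to
    1998", month-name dates ("January 21, 1999", "October 2014"), and bare
    years governed by in/during/since.
    """
    texts = [t.text for t in sentence]
    low = [t.casefold() for t in texts]
    out: list[tuple[int, int, str]] = []
    i = 0
    n = len(texts)
    while i < n:
        if (
            low[i] in ("between", "from")
            and i + 3 < n
            and _is_year(texts[i + 1])
            and low[i + 2] in ("and", "to")
            and _is_year(texts[i + 3])
        ):
            out.append((i, i + 4, "DATE"))
            i += 4
        elif low[i] in _MONTHS:
            j = i + 1
            if j < n and re.fullmatch(r"\d{1,2}", texts[j]):
                j += 1
                if j < n and texts[j] == ",":
                    j += 1
            if j < n and _is_year(texts[j]):
                out.append((i, j + 1, "DATE"))
                i = j + 1
            else:
                i += 1
        elif low[i] in ("in", "during", "since") and i + 1 < n and _is_year(texts[i + 1]):
            out.append((i + 1, i + 2, "DATE"))
            i += 2
        else:
            i += 1
    return out


# ---------------------------------------------------------------------------
# merge + emission
# ---------------------------------------------------------------------------

def merge_spans(spans: Iterable[WeakLabelSpan]) -> list[WeakLabelSpan]:
    """Resolve cross-channel overlaps into a non-overlapping span set.

    Order of preference: higher channel priority, then longer span, then
    leftmost start; fully deterministic and independent of input order.
    """
    unique = sorted(
        set(spans),
        key=lambda s: (
            -s.priority,
            -(s.end - s.start),
            s.sentence_index,
            s.start,
            s.cls.value,
        ),
    )
    accepted: list[WeakLabelSpan] = []
    for span in unique:
        if all(
            span.sentence_index != kept.sentence_index
            or span.end <= kept.start
            or span.start >= kept.end
            for kept in accepted
        ):
            accepted.append(span)
    accepted.sort(key=lambda s: (s.sentence_index, s.start))
    return accepted


def emit_iob2(sentence: Sequence[Token], spans: Iterable[WeakLabelSpan]) -> list[str]:
    """Project non-overlapping spans onto IOB2 tags for one sentence."""
    tags = ["O"] * len(sentence)
    for span in spans:
        if span.end > len(sentence):
            raise ValueError("span exceeds sentence length")
        if any(tags[i] != "O" for i in range(span.start, span.end)):
            raise ValueError("overlapping spans passed to emit_iob2")
        tags[span.start] = f"B-{span.cls.value}"
        for i in range(span.start + 1, span.end):
            tags[i] = f"I-{span.cls.value}"
    validate_iob2(tags)
    return tags


def label_sentence(
    tokens: Sequence[Token],
    gazetteers: Sequence[Gazetteer],
    rules: Sequence[RulePattern] | None = None,
    provider: NERProvider | None = heuristic_ner_provider,
    sentence_index: int = 0,
) -> list[str]:
    spans = (
        distant_label(tokens, gazetteers, sentence_index)
        + prescriptive_label(tokens, rules, sentence_index)
        + noisy_label(tokens, provider, sentence_index)
    )
    return emit_iob2(tokens, merge_spans(spans))


def label_abstract(
    abstract: TokenizedAbstract,
    gazetteers: Sequence[Gazetteer],
    rules: Sequence[RulePattern] | None = None,
    provider: NERProvider | None = heuristic_ner_provider,
) -> LabeledAbstract:
    """Run all three channels over every sentence and emit IOB2 tags.

    ABRV is never produced: no channel targets it.
    """
    sentences = []
    for idx, tokens in enumerate(abstract.sentences):
        tags = label_sentence(tokens, gazetteers, rules, provider, idx)
        sentences.append(LabeledSentence(list(tokens), tags))
    return LabeledAbstract(pmid=abstract.pmid, sentences=sentences)
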