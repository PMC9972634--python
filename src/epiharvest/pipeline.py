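"""End-to-end epidemiologic-information extraction for rare-disease
abstracts.

The flow: a disease query (registry ID or name) is expanded to its full
synonym list; abstracts are acquired from one or more sources and
deduplicated by PMID; an optional STRICT (whole-phrase) or LENIENT
(individual-token) match against the synonym list removes off-target
articles; an epidemiologic-study classifier gates abstracts at probability
0.5 (a probability of exactly 0.5 is kept); and a sequence tagger run over
the preprocessed text yields one record per abstract with the extracted
EPI / STAT / LOC / DATE / SEX / ETHN surface strings.

The study-gating classifier is a pluggable contract. The bundled
:class:`KeywordESClassifier` is a transparent keyword-count stand-in (an
epidemiology-lexicon hit count mapped through a logistic curve), suitable
for offline use and testing; any model exposing ``probability(abstract)``
can replace it.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from math import exp
from pathlib import Path
from typing import Iterable, Protocol, Sequence, runtime_checkable

from .corpus import EntityClass
from .ner_eval import extract_entities
from .preprocess import RawAbstract, preprocess_abstract
from .tagger import SequenceTagger

__all__ = [
    "DiseaseEntry",
    "FilterMode",
    "ESClassifier",
    "KeywordESClassifier",
    "ExtractionRecord",
    "FixtureStore",
    "LookupError_",
    "AmbiguityError",
    "load_disease_dictionary",
    "expand_synonyms",
    "acquire_abstracts",
    "filter_abstracts",
    "identify_diseases",
    "gate_epidemiologic",
    "extract_records",
    "run_pipeline",
]

ENTITY_ORDER = ("EPI", "STAT", "LOC", "DATE", "SEX", "ETHN")


class LookupError_(KeyError):
    """Query resolves to no disease entry."""


class AmbiguityError(ValueError):
    """Query resolves to more than one disease entry."""


@dataclass(frozen=True)
class DiseaseEntry:
    gard_id: str
    name: str
    synonyms: tuple[str, ...] = ()

    @property
    def all_terms(self) -> tuple[str, ...]:
        return (self.name, *self.synonyms)


class FilterMode(str, Enum):
    STRICT = "strict"
    LENIENT = "lenient"
    NONE = "no"


@runtime_checkable
class ESClassifier(Protocol):
    def probability(self, abstract: RawAbstract) -> float:
        ...


#: Lexicon for the keyword stand-in study classifier.
EPI_LEXICON = frozenset(
    {
        "epidemiology", "epidemiologic", "epidemiological",
        "prevalence", "incidence", "occurrence", "frequency",
        "surveillance", "registry", "cohort", "screening",
    }
)


class KeywordESClassifier:
    """Keyword-count stand-in for an epidemiologic-study classifier.

    Counts epidemiology-lexicon word occurrences in title+body and maps the
    count through a logistic curve centred at two hits, so two or more hits
    score >= 0.5. Transparent and deterministic; not a trained model.
    """

    def __init__(self, lexicon: frozenset[str] = EPI_LEXICON, midpoint: float = 2.0):
        self.lexicon = lexicon
        self.midpoint = midpoint

    def probability(self, abstract: RawAbstract) -> float:
        words = re.findall(r"[a-z]+", abstract.text.lower())
        hits = sum(1 for w in words if w in self.lexicon)
        return 1.0 / (1.0 + exp(-(hits - self.midpoint)))


@dataclass
class ExtractionRecord:
    """Per-abstract extraction output: probabilities plus the surface
    strings per entity class, order-preserving and case-insensitively
    deduplicated."""

    pmid: str
    title: str
    epi_prob: float
    entities: dict[str, list[str]] = field(default_factory=dict)


def load_disease_dictionary(source: str | Path | Iterable[str]) -> list[DiseaseEntry]:
    """Read a TSV dictionary: ``gard_id<TAB>name<TAB>pipe|separated|synonyms``."""
    if isinstance(source, (str, Path)):
        lines = Path(source).read_text("utf-8").splitlines()
    else:
        lines = list(source)
    entries = []
    for raw in lines:
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        gard_id, name = parts[0], parts[1]
        synonyms = tuple(
            s.strip() for s in (parts[2].split("|") if len(parts) > 2 and parts[2] else [])
            if s.strip()
        )
        entries.append(DiseaseEntry(gard_id, name, synonyms))
    return entries


def expand_synonyms(query: str, dictionary: Sequence[DiseaseEntry]) -> list[str]:
    """Resolve a registry ID or disease name to its full, case-folded,
    deduplicated synonym list (the canonical name included)."""
    q = query.strip()
    if q.upper().startswith("GARD:"):
        matches = [e for e in dictionary if e.gard_id.upper() == q.upper()]
    else:
        matches = [
            e
            for e in dictionary
            if any(t.casefold() == q.casefold() for t in e.all_terms)
        ]
    if not matches:
        raise LookupError_(f"no dictionary entry for {query!r}")
    if len(matches) > 1:
        raise AmbiguityError(
            f"{query!r} matches {[e.gard_id for e in matches]}"
        )
    seen: dict[str, None] = {}
    for term in matches[0].all_terms:
        seen.setdefault(term.casefold())
    return list(seen)


class FixtureStore:
    """File-backed abstract source: JSON-lines records {pmid, title, abstract}.

    ``search(term)`` returns abstracts whose title or body contains the term
    case-insensitively, in file order.
    """

    def __init__(self, source: str | Path | Iterable[RawAbstract]):
        if isinstance(source, (str, Path)):
            self.abstracts = [
                RawAbstract(str(r["pmid"]), r.get("title", ""), r.get("abstract", ""))
                for r in map(json.loads, Path(source).read_text("utf-8").splitlines())
                if r
            ]
        else:
            self.abstracts = list(source)

    def search(self, term: str) -> list[RawAbstract]:
        t = term.casefold()
        return [a for a in self.abstracts if t in a.text.casefold()]


def acquire_abstracts(
    terms: Sequence[str],
    sources: Sequence[FixtureStore] | FixtureStore,
    max_results: int,
) -> list[RawAbstract]:
    """Union of per-term search hits over all sources, deduplicated by PMID
    in stable first-hit order, capped at ``max_results``."""
    if isinstance(sources, FixtureStore) or hasattr(sources, "search"):
        sources = [sources]
    seen: dict[str, RawAbstract] = {}
    for source in sources:
        for term in terms:
            try:
                hits = source.search(term)
            except Exception as exc:
                raise RuntimeError(f"abstract source {source!r} failed: {exc}") from exc
            for hit in hits:
                seen.setdefault(hit.pmid, hit)
    return list(seen.values())[:max_results]


#: Tokens of multi-word disease terms too generic to key LENIENT matching.
_STOPWORDS = frozenset(
    "a an and the of to due with in for on by type syndrome disease deficiency".split()
)


def _phrase_pattern(term: str) -> re.Pattern:
    return re.compile(rf"(?<!\w){re.escape(term)}(?!\w)", re.I)


def filter_abstracts(
    abstracts: Sequence[RawAbstract],
    terms: Sequence[str],
    mode: FilterMode,
) -> list[RawAbstract]:
    """STRICT keeps abstracts mentioning a whole term; LENIENT keeps those
    mentioning any individual non-stopword token of a term; NONE keeps all.
    STRICT ⊆ LENIENT ⊆ NONE for any term set."""
    if mode is FilterMode.NONE:
        return list(abstracts)
    if not terms:
        raise ValueError("terms required unless mode is NONE")
    if mode is FilterMode.STRICT:
        patterns = [_phrase_pattern(t) for t in terms]
    else:
        tokens = {
            tok
            for term in terms
            for tok in re.findall(r"\w+", term.casefold())
            if tok not in _STOPWORDS
        }
        patterns = [_phrase_pattern(t) for t in tokens]
    return [a for a in abstracts if any(p.search(a.text) for p in patterns)]


def identify_diseases(
    abstract: RawAbstract, dictionary: Sequence[DiseaseEntry]
) -> list[str]:
    """Distinct registry IDs whose name or any synonym occurs as a whole
    phrase in title+body, ordered by first mention."""
    first_offset: dict[str, int] = {}
    text = abstract.text
    for entry in dictionary:
        offsets = [
            m.start()
            for term in entry.all_terms
            for m in [_phrase_pattern(term).search(text)]
            if m
        ]
        if offsets:
            first_offset[entry.gard_id] = min(offsets)
    return sorted(first_offset, key=first_offset.get)


def gate_epidemiologic(
    abstracts: Sequence[RawAbstract],
    classifier: ESClassifier,
    threshold: float = 0.5,
) -> list[tuple[RawAbstract, float]]:
    """Keep abstracts the classifier scores at or above ``threshold``
    (probabilities strictly below the threshold are excluded)."""
    kept = []
    for abstract in abstracts:
        try:
            prob = classifier.probability(abstract)
        except Exception as exc:
            warnings.warn(f"classifier failed on PMID {abstract.pmid}: {exc}",
                          stacklevel=2)
            continue
        if prob >= threshold:
            kept.append((abstract, prob))
    return kept


def _dedup_ci(strings: Iterable[str]) -> list[str]:
    seen: dict[str, str] = {}
    for s in strings:
        seen.setdefault(s.casefold(), s)
    return list(seen.values())


def extract_records(
    gated: Sequence[tuple[RawAbstract, float]],
    tagger: SequenceTagger,
) -> list[ExtractionRecord]:
    """Run preprocessing and the tagger over each gated abstract and
    assemble the per-class entity surface strings.

    Surfaces are recovered from the cleaned sentence text by character
    offsets (falling back to space-joined tokens), kept in first-mention
    order, deduplicated case-insensitively.
    """
    banned = {EntityClass.DIS.value, EntityClass.ABRV.value}
    if banned & {c.value for c in tagger.scheme.classes}:
        raise ValueError("extraction tagger must use a scheme without DIS/ABRV")
    records = []
    for abstract, prob in gated:
        tokenized = preprocess_abstract(abstract)
        tag_seqs = tagger.tag(tokenized.sentences)
        entities: dict[str, list[str]] = {c: [] for c in ENTITY_ORDER}
        for s_idx, (tokens, tags) in enumerate(zip(tokenized.sentences, tag_seqs)):
            text = tokenized.sentence_texts[s_idx]
            for span in extract_entities(tags, s_idx):
                first, last = tokens[span.start], tokens[span.end - 1]
                if 0 <= first.char_start < last.char_end <= len(text):
                    surface = text[first.char_start : last.char_end]
                else:
                    surface = " ".join(t.text for t in tokens[span.start : span.end])
                entities.setdefault(span.cls, []).append(surface)
        records.append(
            ExtractionRecord(
                pmid=abstract.pmid,
                title=abstract.title,
                epi_prob=prob,
                entities={c: _dedup_ci(v) for c, v in entities.items()},
            )
        )
    return records


def run_pipeline(
    query: str,
    dictionary: Sequence[DiseaseEntry],
    sources: Sequence[FixtureStore] | FixtureStore,
    tagger: SequenceTagger,
    max_results: int,
    filter_mode: FilterMode = FilterMode.STRICT,
    classifier: ESClassifier | None = None,
    threshold: float = 0.5,
) -> list[ExtractionRecord]:
    """Synonym expansion → acquisition → filtering → study gating →
    extraction, returning one record per retained abstract."""
    terms = expand_synonyms(query, dictionary)
    abstracts = acquire_abstracts(terms, sources, max_results)
    filtered = filter_abstracts(abstracts, terms, filter_mode)
    gated = gate_epidemiologic(filtered, classifier or KeywordESClassifier(), threshold)
    return extract_records(gated, tagger)
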