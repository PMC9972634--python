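"""Labeled-corpus domain types and IOB2 (CoNLL-style) serialization.

The unit of annotation is a sentence of tokens paired with IOB2 tags drawn
from a :class:`LabelScheme`.  Eight entity classes cover epidemiologic
information in rare-disease abstracts: disease names (DIS), disease
abbreviations (ABRV), epidemiologic type (EPI), epidemiologic rate (STAT),
location (LOC), date (DATE), biological sex (SEX) and
ethnicity/nationality/race (ETHN).

The file dialect is two whitespace-separated columns (token, tag), one blank
line between sentences, and a ``-DOCSTART- <PMID>`` comment line opening each
document.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Iterable, TextIO

import pandas as pd

__all__ = [
    "EntityClass",
    "LabelScheme",
    "Token",
    "LabeledSentence",
    "LabeledAbstract",
    "Corpus",
    "CorpusError",
    "ParseError",
    "SchemeError",
    "ValidationError",
    "validate_iob2",
    "repair_iob2",
    "read_iob2",
    "write_iob2",
    "convert_scheme",
    "label_counts",
    "split_corpus",
]

DOCSTART = "-DOCSTART-"


class CorpusError(Exception):
    """Base class for corpus-layer errors."""


class ParseError(CorpusError):
    """A malformed line in an IOB2 stream (carries the 1-based line number)."""

    def __init__(self, message: str, line_no: int):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


class SchemeError(CorpusError):
    """A tag or class outside the active label scheme."""


class ValidationError(CorpusError):
    """An IOB2 sequence violation (I-X not preceded by B-X/I-X of X)."""


class EntityClass(str, Enum):
    """The closed set of eight entity classes."""

    DIS = "DIS"
    ABRV = "ABRV"
    EPI = "EPI"
    STAT = "STAT"
    LOC = "LOC"
    DATE = "DATE"
    SEX = "SEX"
    ETHN = "ETHN"

    def __str__(self) -> str:  # tags print as bare names
        return self.value


@dataclass(frozen=True)
class LabelScheme:
    """An ordered set of entity classes and its derived IOB2 tag inventory.

    The tag inventory always has ``2 * |classes| + 1`` members: a B- and an
    I- tag per class, plus O.
    """

    name: str
    classes: tuple[EntityClass, ...]

    @property
    def tags(self) -> tuple[str, ...]:
        out = ["O"]
        for cls in self.classes:
            out.append(f"B-{cls.value}")
            out.append(f"I-{cls.value}")
        return tuple(out)

    def __contains__(self, tag: str) -> bool:
        return tag in self.tags

    def tag_to_id(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tags)}


_ALL = (
    EntityClass.DIS,
    EntityClass.ABRV,
    EntityClass.EPI,
    EntityClass.STAT,
    EntityClass.LOC,
    EntityClass.DATE,
    EntityClass.SEX,
    EntityClass.ETHN,
)

#: All eight classes.
STANDARD = LabelScheme("standard", _ALL)
#: ABRV folded into DIS (seven classes).
MERGED_ABRV_DIS = LabelScheme(
    "merged_abrv_dis", tuple(c for c in _ALL if c is not EntityClass.ABRV)
)
#: The final six-class scheme: DIS and ABRV dropped to O.
NO_ABRV_DIS = LabelScheme(
    "no_abrv_dis",
    tuple(c for c in _ALL if c not in (EntityClass.DIS, EntityClass.ABRV)),
)
#: Five classes: additionally drops ETHN.
NO_ABRV_DIS_ETHN = LabelScheme(
    "no_abrv_dis_ethn",
    tuple(
        c
        for c in _ALL
        if c not in (EntityClass.DIS, EntityClass.ABRV, EntityClass.ETHN)
    ),
)

CANONICAL_SCHEMES: dict[str, LabelScheme] = {
    s.name: s for s in (STANDARD, MERGED_ABRV_DIS, NO_ABRV_DIS, NO_ABRV_DIS_ETHN)
}


@dataclass(frozen=True)
class Token:
    """A surface token with optional 0-based half-open character offsets."""

    text: str
    char_start: int = -1
    char_end: int = -1

    def __post_init__(self):
        if not self.text:
            raise ValueError("token text must be non-empty")


@dataclass
class LabeledSentence:
    tokens: list[Token]
    tags: list[str]

    def __post_init__(self):
        if len(self.tokens) != len(self.tags):
            raise ValidationError(
                f"{len(self.tokens)} tokens but {len(self.tags)} tags"
            )

    def __len__(self) -> int:
        return len(self.tokens)

    def texts(self) -> list[str]:
        return [t.text for t in self.tokens]


@dataclass
class LabeledAbstract:
    pmid: str
    sentences: list[LabeledSentence] = field(default_factory=list)


@dataclass
class Corpus:
    name: str
    abstracts: list[LabeledAbstract]
    scheme: LabelScheme

    def sentences(self) -> Iterable[LabeledSentence]:
        for a in self.abstracts:
            yield from a.sentences

    def __len__(self) -> int:
        return len(self.abstracts)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return (
            self.scheme == other.scheme
            and [(a.pmid, [(s.texts(), s.tags) for s in a.sentences]) for a in self.abstracts]
            == [(a.pmid, [(s.texts(), s.tags) for s in a.sentences]) for a in other.abstracts]
        )


def validate_iob2(tags: list[str], scheme: LabelScheme | None = None) -> None:
    """Raise on tags outside ``scheme`` or an I- tag without a valid opener."""
    prev = "O"
    for i, tag in enumerate(tags):
        if scheme is not None and tag not in scheme:
            raise SchemeError(f"tag {tag!r} not in scheme {scheme.name!r}")
        if tag.startswith("I-"):
            cls = tag[2:]
            if prev not in (f"B-{cls}", f"I-{cls}"):
                raise ValidationError(
                    f"position {i}: {tag!r} follows {prev!r}"
                )
        prev = tag


def repair_iob2(tags: list[str]) -> list[str]:
    """Conservatively repair a predicted sequence: a dangling I-X becomes B-X."""
    out: list[str] = []
    prev = "O"
    for tag in tags:
        if tag.startswith("I-"):
            cls = tag[2:]
            if prev not in (f"B-{cls}", f"I-{cls}"):
                tag = f"B-{cls}"
        out.append(tag)
        prev = tag
    return out


def read_iob2(stream: TextIO | Iterable[str], scheme: LabelScheme,
              name: str = "custom") -> Corpus:
    """Parse a two-column IOB2 stream into a validated :class:`Corpus`.

    Documents are opened by ``-DOCSTART- <PMID>`` lines; sentences are
    separated by blank lines. Round-trips byte-identically through
    :func:`write_iob2` modulo a trailing newline.
    """
    abstracts: list[LabeledAbstract] = []
    current: LabeledAbstract | None = None
    tok_buf: list[Token] = []
    tag_buf: list[str] = []
    sent_index = 0

    def flush_sentence(line_no: int) -> None:
        nonlocal tok_buf, tag_buf, sent_index
        if not tok_buf:
            return
        try:
            validate_iob2(tag_buf, scheme)
        except ValidationError as exc:
            raise ValidationError(f"sentence {sent_index}: {exc}") from exc
        if current is None:
            raise ParseError("token line before any -DOCSTART-", line_no)
        current.sentences.append(LabeledSentence(tok_buf, tag_buf))
        tok_buf, tag_buf = [], []
        sent_index += 1

    line_no = 0
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if line.startswith(DOCSTART):
            flush_sentence(line_no)
            if current is not None:
                abstracts.append(current)
            pmid = line[len(DOCSTART):].strip()
            current = LabeledAbstract(pmid=pmid)
            sent_index = 0
            continue
        if not line.strip():
            flush_sentence(line_no)
            continue
        cols = line.split()
        if len(cols) != 2:
            raise ParseError(f"expected 2 columns, got {len(cols)}", line_no)
        text, tag = cols
        if tag not in scheme:
            raise SchemeError(
                f"line {line_no}: tag {tag!r} not in scheme {scheme.name!r}"
            )
        tok_buf.append(Token(text))
        tag_buf.append(tag)
    flush_sentence(line_no + 1)
    if current is not None:
        abstracts.append(current)
    return Corpus(name=name, abstracts=abstracts, scheme=scheme)


def write_iob2(corpus: Corpus) -> str:
    """Serialize a corpus to the two-column IOB2 dialect read by read_iob2."""
    lines: list[str] = []
    for abstract in corpus.abstracts:
        lines.append(f"{DOCSTART} {abstract.pmid}".rstrip())
        for sent in abstract.sentences:
            for tok, tag in zip(sent.tokens, sent.tags):
                lines.append(f"{tok.text} {tag}")
            lines.append("")
    return "\n".join(lines)


def _convert_tags(tags: list[str], source: LabelScheme,
                  target: LabelScheme) -> list[str]:
    merged = (
        EntityClass.ABRV not in target.classes
        and EntityClass.DIS in target.classes
        and EntityClass.ABRV in source.classes
    )
    keep = {c.value for c in target.classes}
    out: list[str] = []
    for tag in tags:
        if tag == "O":
            out.append("O")
            continue
        prefix, cls = tag.split("-", 1)
        if merged and cls == "ABRV":
            # B-ABRV stays a B- boundary: two adjacent entities never fuse.
            out.append(f"{prefix}-DIS")
        elif cls in keep:
            out.append(tag)
        else:
            out.append("O")
    return out


def convert_scheme(corpus: Corpus, target: LabelScheme) -> Corpus:
    """Re-express a corpus under a different label scheme.

    Classes absent from ``target`` become O; under a merged scheme ABRV tags
    are relabeled as DIS with their B- boundaries preserved.
    """
    mergeable = {EntityClass.ABRV} if EntityClass.DIS in target.classes else set()
    missing = set(target.classes) - set(corpus.scheme.classes) - mergeable
    if missing:
        raise SchemeError(
            f"target classes {sorted(c.value for c in missing)} absent from source"
        )
    abstracts = [
        LabeledAbstract(
            pmid=a.pmid,
            sentences=[
                LabeledSentence(
                    list(s.tokens),
                    _convert_tags(s.tags, corpus.scheme, target),
                )
                for s in a.sentences
            ],
        )
        for a in corpus.abstracts
    ]
    out = Corpus(name=corpus.name, abstracts=abstracts, scheme=target)
    for s in out.sentences():
        validate_iob2(s.tags, target)
    return out


def _pct(numer: int, denom: int) -> float:
    if denom == 0:
        return 0.0
    q = Decimal(numer) * 100 / Decimal(denom)
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def label_counts(corpus: Corpus) -> pd.DataFrame:
    """Per-class labeled-token counts with the two percentage columns
    reported for annotation accounting: each class's share of non-O labels,
    and the non-O share of all tokens (summary row)."""
    counts = {c.value: 0 for c in corpus.scheme.classes}
    total_tokens = 0
    for sent in corpus.sentences():
        total_tokens += len(sent)
        for tag in sent.tags:
            if tag != "O":
                counts[tag[2:]] += 1
    non_o = sum(counts.values())
    rows = [
        {
            "label": cls,
            "count": n,
            "pct_of_labels": _pct(n, non_o),
        }
        for cls, n in counts.items()
    ]
    rows.append(
        {
            "label": "ALL",
            "count": non_o,
            "pct_of_labels": _pct(non_o, total_tokens),
        }
    )
    df = pd.DataFrame(rows).set_index("label")
    df.attrs["total_tokens"] = total_tokens
    return df


def split_corpus(
    corpus: Corpus,
    test_n: int = 50,
    val_ratio: float = 0.2,
    seed: int = 42,
) -> tuple[Corpus, Corpus, Corpus]:
    """Randomly partition abstracts into (train, validation, test).

    ``test_n`` abstracts are drawn first; the remainder is split with a
    hold-out fraction of ``val_ratio``. Deterministic for a given seed;
    the three parts are disjoint and exhaustive.
    """
    n = len(corpus.abstracts)
    if not 0 < test_n < n:
        raise ValueError(f"test_n={test_n} must be in (0, {n})")
    if not 0 < val_ratio < 1:
        raise ValueError("val_ratio must be in (0, 1)")
    order = list(range(n))
    random.Random(seed).shuffle(order)
    test_idx = order[:test_n]
    rest = order[test_n:]
    val_n = round(len(rest) * val_ratio)
    val_idx, train_idx = rest[:val_n], rest[val_n:]

    def sub(name: str, idx: list[int]) -> Corpus:
        return Corpus(name, [corpus.abstracts[i] for i in sorted(idx)], corpus.scheme)

    return sub("train", train_idx), sub("validation", val_idx), sub("test", test_idx)
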