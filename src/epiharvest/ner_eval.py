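"""Entity-level and token-level evaluation of IOB2 sequence tagging.

Entity-level evaluation treats every maximal B-/I- run as one unit: a
predicted span is a true positive only when its class, start and end all
match a gold span, so a single misclassified token inside a multi-token
entity voids the whole entity. Denominators are span counts.

Token-level evaluation strips the B-/I- prefix and scores each token's
class independently; the worked example is gold (B-EPI, I-EPI, I-EPI)
against prediction (B-EPI, I-EPI, O), which gives EPI recall 2/3 at the
token level while the entity level scores it fully incorrect.

Overall rows are micro-averages: true/false positive/negative counts are
pooled across the non-O classes before computing precision, recall and F1.
Token accuracy (which does include O) is reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .corpus import Corpus, EntityClass, repair_iob2

__all__ = [
    "EvalLevel",
    "EntitySpan",
    "ClassMetrics",
    "EvalReport",
    "f1",
    "extract_entities",
    "entity_level_metrics",
    "token_level_metrics",
    "evaluate",
]

TagSequences = list[list[str]]


class EvalLevel(str, Enum):
    ENTITY = "entity"
    TOKEN = "token"


@dataclass(frozen=True)
class EntitySpan:
    """A maximal entity run over half-open token indices."""

    cls: str
    sentence_index: int
    start: int
    end: int


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass
class EvalReport:
    level: EvalLevel
    per_class: dict[str, ClassMetrics]
    overall: ClassMetrics
    accuracy: float | None = None  # token level only
    counts: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def to_dataframe(self, digits: int = 3) -> pd.DataFrame:
        rows = {"Overall": self.overall, **self.per_class}
        df = pd.DataFrame(
            {
                name: {
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                    "support": m.support,
                }
                for name, m in rows.items()
            }
        ).T
        df[["precision", "recall", "f1"]] = df[["precision", "recall", "f1"]].round(digits)
        df["support"] = df["support"].astype(int)
        return df


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def _as_tag_sequences(obj: Corpus | TagSequences) -> TagSequences:
    if isinstance(obj, Corpus):
        return [s.tags for s in obj.sentences()]
    return obj


def extract_entities(tags: list[str], sentence_index: int = 0) -> list[EntitySpan]:
    """Decode maximal B-/I- runs into spans.

    A dangling I-X (after O or a different class) is repaired to B-X first,
    the conservative convention for possibly-invalid predictions.
    """
    tags = repair_iob2(tags)
    spans: list[EntitySpan] = []
    start, cls = None, None
    for i, tag in enumerate(tags):
        if tag.startswith("B-"):
            if start is not None:
                spans.append(EntitySpan(cls, sentence_index, start, i))
            start, cls = i, tag[2:]
        elif tag.startswith("I-"):
            continue  # guaranteed same-class continuation after repair
        else:
            if start is not None:
                spans.append(EntitySpan(cls, sentence_index, start, i))
            start, cls = None, None
    if start is not None:
        spans.append(EntitySpan(cls, sentence_index, start, len(tags)))
    return spans


def _check_alignment(gold: TagSequences, pred: TagSequences) -> None:
    if len(gold) != len(pred) or any(
        len(g) != len(p) for g, p in zip(gold, pred)
    ):
        raise ValueError("gold and predicted tag sequences are not aligned")


def _classes_present(gold: TagSequences, pred: TagSequences) -> list[str]:
    seen = {
        t[2:]
        for seq in (*gold, *pred)
        for t in seq
        if t != "O"
    }
    order = [c.value for c in EntityClass]
    return sorted(seen, key=lambda c: order.index(c) if c in order else len(order))


def _report(level: EvalLevel,
            counts: dict[str, tuple[int, int, int]],
            accuracy: float | None = None) -> EvalReport:
    def metrics(tp: int, fp: int, fn: int) -> ClassMetrics:
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        return ClassMetrics(p, r, f1(p, r), support=tp + fn)

    per_class = {c: metrics(*cnt) for c, cnt in counts.items()}
    pooled = tuple(sum(c[i] for c in counts.values()) for i in range(3))
    return EvalReport(
        level=level,
        per_class=per_class,
        overall=metrics(*pooled),
        accuracy=accuracy,
        counts=dict(counts),
    )


def entity_level_metrics(gold: Corpus | TagSequences,
                         pred: Corpus | TagSequences) -> EvalReport:
    """Exact-span matching: TP iff class, start and end all agree."""
    gold, pred = _as_tag_sequences(gold), _as_tag_sequences(pred)
    _check_alignment(gold, pred)
    counts: dict[str, tuple[int, int, int]] = {}
    gold_spans: set[EntitySpan] = set()
    pred_spans: set[EntitySpan] = set()
    for i, (g, p) in enumerate(zip(gold, pred)):
        gold_spans.update(extract_entities(g, i))
        pred_spans.update(extract_entities(p, i))
    for cls in _classes_present(gold, pred):
        g_c = {s for s in gold_spans if s.cls == cls}
        p_c = {s for s in pred_spans if s.cls == cls}
        tp = len(g_c & p_c)
        counts[cls] = (tp, len(p_c) - tp, len(g_c) - tp)
    return _report(EvalLevel.ENTITY, counts)


def token_level_metrics(gold: Corpus | TagSequences,
                        pred: Corpus | TagSequences) -> EvalReport:
    """Prefix-stripped per-token scoring; accuracy includes the O class,
    the micro-averaged overall row does not."""
    gold, pred = _as_tag_sequences(gold), _as_tag_sequences(pred)
    _check_alignment(gold, pred)
    counts: dict[str, tuple[int, int, int]] = {}
    pairs = [
        (g[2:] if g != "O" else "O", p[2:] if p != "O" else "O")
        for gs, ps in zip(gold, pred)
        for g, p in zip(gs, ps)
    ]
    total = len(pairs)
    correct_tags = sum(
        g == p
        for gs, ps in zip(gold, pred)
        for g, p in zip(gs, ps)
    )
    for cls in _classes_present(gold, pred):
        tp = sum(1 for g, p in pairs if g == cls and p == cls)
        fp = sum(1 for g, p in pairs if g != cls and p == cls)
        fn = sum(1 for g, p in pairs if g == cls and p != cls)
        counts[cls] = (tp, fp, fn)
    accuracy = correct_tags / total if total else 0.0
    return _report(EvalLevel.TOKEN, counts, accuracy=accuracy)


def evaluate(gold: Corpus | TagSequences,
             pred: Corpus | TagSequences) -> dict[EvalLevel, EvalReport]:
    """Both evaluation levels at once."""
    return {
        EvalLevel.ENTITY: entity_level_metrics(gold, pred),
        EvalLevel.TOKEN: token_level_metrics(gold, pred),
    }
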