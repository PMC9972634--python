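"""Sequence-tagger contract, the rule-based reference tagger, and a
desk-scale fine-tuning harness.

Any tagger maps token sequences to IOB2 tag sequences under a declared
:class:`~epiharvest.corpus.LabelScheme`; the output layer of a neural
tagger needs ``2n + 1`` nodes for ``n`` entity classes (a B- and I- node
per class plus O).

Two implementations ship here:

* :class:`RuleTagger` — inference-mode reuse of the weak-supervision
  channels; download-free and fully deterministic.
* :func:`finetune` — trains a token-classification head (AdamW, softmax
  cross-entropy, implemented in numpy) on top of a frozen feature encoder.
  The bundled :class:`HashingEncoder` is a tiny randomly-initialized
  two-layer encoder over hashed word features; any object with an
  ``encode(texts) -> (n, dim) array`` method can stand in, so a real
  pretrained backbone can be plugged in where available.

The default hyperparameters are the reference fine-tuning configuration:
4 epochs, learning rate 5e-5, weight decay 0.01, max sequence length 128,
batch sizes 16/8, seed 42, AdamW (0.9, 0.99, 1e-8), dropout 0.1 and
initialization std 0.02.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .corpus import Corpus, LabelScheme, NO_ABRV_DIS, Token, repair_iob2
from .ner_eval import EvalLevel, EvalReport, evaluate
from . import weak_labeler

__all__ = [
    "SequenceTagger",
    "FineTuneConfig",
    "OPTIMIZED_PRESET",
    "OptionalComponentError",
    "output_head_size",
    "RuleTagger",
    "rule_tagger",
    "align_labels_to_subwords",
    "project_subword_labels",
    "HashingEncoder",
    "HeadTagger",
    "finetune",
    "IGNORE_INDEX",
]

IGNORE_INDEX = -100


@runtime_checkable
class SequenceTagger(Protocol):
    scheme: LabelScheme

    def tag(self, sentences: Sequence[Sequence[Token]]) -> list[list[str]]:
        ...


class OptionalComponentError(RuntimeError):
    """An optional component (e.g. a pretrained backbone) is unavailable."""


def output_head_size(scheme: LabelScheme) -> int:
    """Nodes required in a token-classification output layer: 2n + 1."""
    return 2 * len(scheme.classes) + 1


@dataclass
class FineTuneConfig:
    epochs: int = 4
    learning_rate: float = 5e-5
    weight_decay: float = 0.01
    max_seq_len: int = 128
    train_batch: int = 16
    eval_batch: int = 8
    seed: int = 42
    adam_beta1: float = 0.9
    adam_beta2: float = 0.99
    adam_eps: float = 1e-8
    dropout: float = 0.1
    warmup_ratio: float = 0.0
    scheduler: str = "linear"
    grad_accum: int = 1
    init_std: float = 0.02

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{k}={v}\n" for k, v in asdict(self).items()), "utf-8"
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "FineTuneConfig":
        types = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for line in Path(path).read_text("utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, value = line.split("=", 1)
            kind = types[key]
            kwargs[key] = (
                int(value) if kind == "int"
                else float(value) if kind == "float"
                else value
            )
        return cls(**kwargs)


#: The grid-search winner: the published epsilon, warm-up ratio and linear
#: scheduler, with the learning rate taken from the search grid (the printed
#: 3e-8 lies outside the grid and is read as a typo for 3e-5).
OPTIMIZED_PRESET = FineTuneConfig(
    learning_rate=3e-5, adam_eps=1e-6, warmup_ratio=0.06
)


class RuleTagger:
    """Deterministic reference tagger reusing the weak-supervision channels.

    Classes outside ``scheme`` are suppressed from the emitted tags, so the
    same resources can serve the 8-class and 6-class configurations.
    """

    def __init__(
        self,
        gazetteers: Sequence[weak_labeler.Gazetteer],
        rules: Sequence[weak_labeler.RulePattern] | None = None,
        provider: weak_labeler.NERProvider | None = weak_labeler.heuristic_ner_provider,
        scheme: LabelScheme = NO_ABRV_DIS,
    ):
        self.gazetteers = list(gazetteers)
        self.rules = list(rules) if rules is not None else weak_labeler.bundled_rules()
        self.provider = provider
        self.scheme = scheme

    def tag(self, sentences: Sequence[Sequence[Token]]) -> list[list[str]]:
        out = []
        for idx, tokens in enumerate(sentences):
            if not tokens:
                out.append([])
                continue
            tags = weak_labeler.label_sentence(
                tokens, self.gazetteers, self.rules, self.provider, idx
            )
            out.append([t if t in self.scheme else "O" for t in tags])
        return out


def rule_tagger(
    gazetteers: Sequence[weak_labeler.Gazetteer] | None = None,
    rules: Sequence[weak_labeler.RulePattern] | None = None,
    scheme: LabelScheme = NO_ABRV_DIS,
) -> RuleTagger:
    """The bundled-resource rule tagger (six-class scheme by default)."""
    if gazetteers is None:
        include_dis = any(c.value == "DIS" for c in scheme.classes)
        gazetteers = weak_labeler.bundled_gazetteers(include_diseases=include_dis)
    return RuleTagger(gazetteers, rules, scheme=scheme)


# ---------------------------------------------------------------------------
# subword alignment
# ---------------------------------------------------------------------------

def align_labels_to_subwords(
    tokens: Sequence[Token],
    tags: Sequence[str],
    subword_map: Sequence[Sequence[int]],
    scheme: LabelScheme,
    max_len: int | None = None,
) -> list[int]:
    """Project word-level tags onto subword positions.

    The first subword of each word carries the word's label id; continuation
    subwords carry :data:`IGNORE_INDEX`. Optionally truncates label ids and
    inputs consistently at ``max_len`` subwords.
    """
    if len(subword_map) != len(tokens):
        raise ValueError("subword_map must cover every word")
    tag_ids = scheme.tag_to_id()
    n_subwords = sum(len(m) for m in subword_map)
    out = [IGNORE_INDEX] * n_subwords
    pos = 0
    for tag, positions in zip(tags, subword_map):
        if not positions:
            raise ValueError("word with no subword positions")
        out[pos] = tag_ids[tag]
        pos += len(positions)
    if max_len is not None:
        out = out[:max_len]
    return out


def project_subword_labels(
    subword_labels: Sequence[int],
    subword_map: Sequence[Sequence[int]],
    scheme: LabelScheme,
) -> list[str]:
    """Inverse of :func:`align_labels_to_subwords` for untruncated input."""
    tags = []
    pos = 0
    for positions in subword_map:
        tags.append(scheme.tags[subword_labels[pos]])
        pos += len(positions)
    return tags


# ---------------------------------------------------------------------------
# numpy fine-tuning harness
# ---------------------------------------------------------------------------

class HashingEncoder:
    """Frozen two-layer encoder over hashed word identities.

    Each distinct (casefolded) word hashes to a pseudo-random embedding;
    a fixed tanh layer mixes it with a shape feature (digits/caps/length).
    Deterministic given the seed. Not trained — it plays the role of a
    pretrained backbone at desk scale.
    """

    def __init__(self, dim: int = 128, seed: int = 42):
        self.dim = dim
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._mix = rng.normal(0.0, 1.0 / math.sqrt(dim), size=(dim + 4, dim))

    def _word_vector(self, text: str) -> np.ndarray:
        # stable across processes (unlike builtin str hashing)
        h = zlib.crc32(f"{self.seed}:{text.casefold()}".encode("utf-8"))
        rng = np.random.default_rng(h)
        vec = rng.normal(0.0, 1.0, size=self.dim)
        shape = np.array(
            [
                float(text.isdigit()),
                float(text[0].isupper()),
                float(any(ch.isdigit() for ch in text)),
                min(len(text), 12) / 12.0,
            ]
        )
        return np.concatenate([vec, shape])

    def encode(self, texts: Sequence[str]) -> np.ndarray:
        if not texts:
            return np.zeros((0, self.dim))
        raw = np.stack([self._word_vector(t) for t in texts])
        return np.tanh(raw @ self._mix)


class HeadTagger:
    """A trained linear token-classification head over a frozen encoder."""

    def __init__(self, encoder, weights: np.ndarray, bias: np.ndarray,
                 scheme: LabelScheme):
        self.encoder = encoder
        self.weights = weights
        self.bias = bias
        self.scheme = scheme

    def logits(self, texts: Sequence[str]) -> np.ndarray:
        return self.encoder.encode(texts) @ self.weights + self.bias

    def tag(self, sentences: Sequence[Sequence[Token]]) -> list[list[str]]:
        tags_out = []
        for tokens in sentences:
            if not tokens:
                tags_out.append([])
                continue
            ids = self.logits([t.text for t in tokens]).argmax(axis=1)
            tags_out.append(repair_iob2([self.scheme.tags[i] for i in ids]))
        return tags_out


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    reports: dict[EvalLevel, EvalReport]


def finetune(
    corpus_train: Corpus,
    corpus_val: Corpus,
    config: FineTuneConfig | None = None,
    backbone=None,
) -> tuple[HeadTagger, list[EpochRecord]]:
    """Train a 2n+1-node classification head on top of ``backbone``.

    Per epoch the model is evaluated on the validation corpus at both
    levels. AdamW with decoupled weight decay and the configured scheduler
    drive the updates; everything is seeded and single-threaded.
    """
    if backbone is None:
        raise OptionalComponentError(
            "no encoder backbone supplied; pass e.g. HashingEncoder()"
        )
    if corpus_train.scheme != corpus_val.scheme:
        raise ValueError("train and validation corpora must share one scheme")
    config = config or FineTuneConfig()
    scheme = corpus_train.scheme
    n_out = output_head_size(scheme)
    tag_ids = scheme.tag_to_id()

    sents = [s for s in corpus_train.sentences() if len(s) > 0]
    X = backbone.encode(
        [t.text for s in sents for t in s.tokens[: config.max_seq_len]]
    )
    y = np.array(
        [tag_ids[tag] for s in sents for tag in s.tags[: config.max_seq_len]]
    )
    dim = X.shape[1]

    rng = np.random.default_rng(config.seed)
    W = rng.normal(0.0, config.init_std, size=(dim, n_out))
    b = np.zeros(n_out)
    mW = np.zeros_like(W); vW = np.zeros_like(W)
    mb = np.zeros_like(b); vb = np.zeros_like(b)
    t_step = 0

    n = len(y)
    steps_per_epoch = max(1, math.ceil(n / config.train_batch))
    total_steps = steps_per_epoch * config.epochs
    warmup = int(config.warmup_ratio * total_steps)

    def lr_at(step: int) -> float:
        base = config.learning_rate
        if warmup and step < warmup:
            return base * (step + 1) / warmup
        frac = (step - warmup) / max(1, total_steps - warmup)
        if config.scheduler == "cosine":
            return base * 0.5 * (1 + math.cos(math.pi * frac))
        return base * max(0.0, 1 - frac)  # linear decay

    val_sentences = [[t for t in s.tokens] for s in corpus_val.sentences()]
    val_gold = [s.tags for s in corpus_val.sentences()]
    history: list[EpochRecord] = []
    model = HeadTagger(backbone, W, b, scheme)

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.train_batch):
            idx = order[start : start + config.train_batch]
            xb, yb = X[idx], y[idx]
            if config.dropout > 0:
                mask = rng.random(xb.shape) >= config.dropout
                xb = xb * mask / (1 - config.dropout)
            logits = xb @ W + b
            logits -= logits.max(axis=1, keepdims=True)
            expl = np.exp(logits)
            probs = expl / expl.sum(axis=1, keepdims=True)
            loss = -np.log(probs[np.arange(len(yb)), yb] + 1e-12).mean()
            epoch_loss += loss * len(yb)

            grad = probs
            grad[np.arange(len(yb)), yb] -= 1.0
            grad /= len(yb)
            gW = xb.T @ grad
            gb = grad.sum(axis=0)

            t_step += 1
            lr = lr_at(t_step - 1)
            for param, g, m, v in ((W, gW, mW, vW), (b, gb, mb, vb)):
                m *= config.adam_beta1
                m += (1 - config.adam_beta1) * g
                v *= config.adam_beta2
                v += (1 - config.adam_beta2) * g * g
                mhat = m / (1 - config.adam_beta1**t_step)
                vhat = v / (1 - config.adam_beta2**t_step)
                param -= lr * (
                    mhat / (np.sqrt(vhat) + config.adam_eps)
                    + config.weight_decay * param
                )
        reports = evaluate(val_gold, model.tag(val_sentences))
        history.append(EpochRecord(epoch, epoch_loss / n, reports))

    return model, history
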