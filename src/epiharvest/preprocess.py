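"""Abstract cleaning, sentence splitting, tokenization and token repair.

Abstracts arrive as noisy plain text (HTML remnants, stray markup
characters, thousand-separator commas that break tokenizers). The cleaning
pass deletes exactly those; stopwords are kept, because downstream
contextual models use them. Splitting and tokenization are rule-based and
offset-preserving, followed by a repair pass that undoes the classic
tokenizer errata on numerals: whitespace tokens, digit groups split at
thousand separators ("1 000 000"), and sentence breaks inside a number.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .corpus import Token

__all__ = [
    "RawAbstract",
    "TokenizedAbstract",
    "clean_text",
    "split_sentences",
    "tokenize",
    "repair_tokens",
    "preprocess_abstract",
]


@dataclass
class RawAbstract:
    pmid: str
    title: str
    body: str

    @property
    def text(self) -> str:
        return f"{self.title} {self.body}".strip() if self.title else self.body


@dataclass
class TokenizedAbstract:
    pmid: str
    sentences: list[list[Token]] = field(default_factory=list)
    sentence_texts: list[str] = field(default_factory=list)


_TAG_RE = re.compile(r"<[^<>]+>")
_XML_ENTITIES = {
    "&amp;": "&",
    "&lt;": "<",
    "&gt;": ">",
    "&quot;": '"',
    "&apos;": "'",
}
_NUM_COMMA_RE = re.compile(r"(?<=\d),(?=\d)")
_EXTRANEOUS = str.maketrans("", "", "*^$")


def clean_text(raw: str) -> str:
    """Remove HTML remnants, the stray characters ``* ^ $``, and commas
    inside digit groups. Everything else — including stopwords — is kept."""
    text = _TAG_RE.sub(" ", raw)
    for ent, char in _XML_ENTITIES.items():
        text = text.replace(ent, char)
    text = text.translate(_EXTRANEOUS)
    text = _NUM_COMMA_RE.sub("", text)
    # collapse whitespace runs introduced by tag removal
    text = re.sub(r"[ \t]{2,}", " ", text)
    return text.strip()


# Sentences end at . ! ? followed by whitespace and an upper-case/digit
# opener, unless the period closes a known abbreviation or an initial.
_ABBREVS = (
    "e.g", "i.e", "etc", "et al", "cf", "vs", "approx", "ca", "fig",
    "figs", "dr", "prof", "no", "vol", "st",
)
_SENT_BOUNDARY = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9(\"'])")


def _ends_with_abbrev(chunk: str) -> bool:
    lowered = chunk.rstrip().lower()
    if re.search(r"(?:^|\s)[a-z]\.$", lowered):  # single-letter initial
        return True
    return any(lowered.endswith(a + ".") for a in _ABBREVS)


def split_sentences(text: str) -> list[str]:
    """Split cleaned text into sentences; concatenation of the result
    reconstructs the text modulo inter-sentence whitespace."""
    if not text.strip():
        return []
    pieces = _SENT_BOUNDARY.split(text)
    sentences: list[str] = []
    for piece in pieces:
        if sentences and _ends_with_abbrev(sentences[-1]):
            sentences[-1] = f"{sentences[-1]} {piece}"
        else:
            sentences.append(piece)
    return [s.strip() for s in sentences if s.strip()]


# Words (with internal hyphens/apostrophes kept out: punctuation is split
# off), decimal numbers, and single punctuation marks.
_TOKEN_RE = re.compile(r"\d+(?:\.\d+)?|\w+|[^\w\s]", re.UNICODE)


def tokenize(sentence: str) -> list[Token]:
    """Tokenize one sentence; tokens carry 0-based half-open offsets."""
    return [
        Token(m.group(), m.start(), m.end())
        for m in _TOKEN_RE.finditer(sentence)
    ]


_DIGITS_RE = re.compile(r"\d+$")


def _merge_number_runs(tokens: list[Token]) -> list[Token]:
    """Re-combine "1 000 000"-style splits: a 1-3 digit token followed by
    3-digit groups, each separated by exactly one space (gap unknown for
    synthetic offsets, assumed one space)."""
    out: list[Token] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        if _DIGITS_RE.fullmatch(tok.text) and len(tok.text) <= 3:
            j = i
            while j + 1 < len(tokens):
                nxt = tokens[j + 1]
                if not (_DIGITS_RE.fullmatch(nxt.text) and len(nxt.text) == 3):
                    break
                gap_known = tokens[j].char_end >= 0 and nxt.char_start >= 0
                if gap_known and nxt.char_start - tokens[j].char_end != 1:
                    break
                j += 1
            if j > i:
                merged = "".join(t.text for t in tokens[i : j + 1])
                out.append(Token(merged, tok.char_start, tokens[j].char_end))
                i = j + 1
                continue
        out.append(tok)
        i += 1
    return out


def repair_tokens(sentences: list[list[Token]]) -> list[list[Token]]:
    """Errata-repair pass: drop whitespace tokens, merge split numbers, and
    re-join a sentence break that landed inside a number. Idempotent;
    non-ASCII characters (a, b, β, …) pass through untouched."""
    cleaned = [
        [t for t in sent if t.text.strip()] for sent in sentences
    ]
    cleaned = [s for s in cleaned if s]

    rejoined: list[list[Token]] = []
    for sent in cleaned:
        prev = rejoined[-1] if rejoined else None
        starts_with_digits = bool(_DIGITS_RE.fullmatch(sent[0].text))
        prev_split_number = (
            prev is not None
            and len(prev) >= 2
            and prev[-1].text == "."
            and bool(_DIGITS_RE.fullmatch(prev[-2].text))
        )
        if starts_with_digits and prev_split_number:
            prev.extend(sent)
        else:
            rejoined.append(list(sent))

    return [_merge_number_runs(sent) for sent in rejoined]


def preprocess_abstract(raw: RawAbstract) -> TokenizedAbstract:
    """clean → split → tokenize → repair, keeping per-sentence source text
    so entity surfaces can later be recovered by character offsets."""
    text = clean_text(raw.text)
    sents = split_sentences(text)
    tokenized = [tokenize(s) for s in sents]
    repaired = repair_tokens(tokenized)
    # repair may drop or fuse sentences; recover each sentence's text from
    # the tokens' source sentence where offsets are still consistent
    texts: list[str] = []
    ti = 0
    for sent in repaired:
        # find the source sentence containing this repaired sentence's tokens
        while ti < len(sents) and not _covers(sents[ti], sent):
            ti += 1
        texts.append(sents[ti] if ti < len(sents) else " ".join(t.text for t in sent))
    return TokenizedAbstract(pmid=raw.pmid, sentences=repaired, sentence_texts=texts)


def _covers(sentence: str, tokens: list[Token]) -> bool:
    """True when every token's offsets index its own text within
    ``sentence`` (merged number tokens may span former spaces)."""
    for t in tokens:
        if t.char_start < 0 or t.char_end > len(sentence):
            return False
        if sentence[t.char_start : t.char_end].replace(" ", "") != t.text:
            return False
    return True
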