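"""Independent brute-force oracles for the evaluation engine.

These deliberately avoid the library's span decoder and confusion logic:
entity spans are found by testing every (start, end, class) triple, and
token counts by direct per-pair tallies.
"""

from collections import Counter


def _spans_brute_force(tags, sentence_index):
    spans = set()
    n = len(tags)
    classes = {t[2:] for t in tags if t != "O"}
    for start in range(n):
        for end in range(start + 1, n + 1):
            for cls in classes:
                if (
                    tags[start] == f"B-{cls}"
                    and all(t == f"I-{cls}" for t in tags[start + 1 : end])
                    and (end == n or tags[end] != f"I-{cls}")
                ):
                    spans.add((cls, sentence_index, start, end))
    return spans


def entity_oracle_counts(gold, pred):
    """class -> (tp, fp, fn) by exhaustive span enumeration."""
    g_spans, p_spans = set(), set()
    for i, (g, p) in enumerate(zip(gold, pred)):
        g_spans |= _spans_brute_force(g, i)
        p_spans |= _spans_brute_force(p, i)
    classes = {s[0] for s in g_spans | p_spans}
    out = {}
    for cls in classes:
        gc = {s for s in g_spans if s[0] == cls}
        pc = {s for s in p_spans if s[0] == cls}
        tp = len(gc & pc)
        out[cls] = (tp, len(pc) - tp, len(gc) - tp)
    return out


def token_oracle_counts(gold, pred):
    """class -> (tp, fp, fn) by direct per-token tallies, prefix stripped."""
    tally = Counter()
    for g_seq, p_seq in zip(gold, pred):
        for g, p in zip(g_seq, p_seq):
            tally[(g[2:] if g != "O" else "O", p[2:] if p != "O" else "O")] += 1
    classes = {c for pair in tally for c in pair if c != "O"}
    out = {}
    for cls in classes:
        tp = tally[(cls, cls)]
        fp = sum(v for (g, p), v in tally.items() if p == cls and g != cls)
        fn = sum(v for (g, p), v in tally.items() if g == cls and p != cls)
        out[cls] = (tp, fp, fn)
    return out
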