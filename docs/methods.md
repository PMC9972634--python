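# Methods

## Problem and scope

`epiharvest` implements an offline toolkit for mining epidemiologic
information (EI) — prevalence and incidence rates with their context
(location, date, sex, ethnicity) — from rare-disease PubMed-style
abstracts. It covers corpus construction by weak supervision, dual-level
NER evaluation, a pluggable tagging layer with a desk-scale training
harness, an end-to-end extraction pipeline, and per-100,000 rate
normalization for comparison with curated registry data.

## Entity model and label schemes

Eight entity classes are annotated: disease names (DIS), disease
abbreviations (ABRV), epidemiologic type (EPI, e.g. "point prevalence"),
epidemiologic rate (STAT, e.g. "1 in 40,760"), location (LOC), date
(DATE), biological sex (SEX) and ethnicity/nationality/race (ETHN). Tags
follow IOB2: B-X opens an entity, I-X continues it, O is outside; a valid
I-X must follow B-X or I-X of the same class. For n classes a neural
token classifier therefore needs 2n+1 output nodes.

Four canonical scheme variants are provided: all eight classes; ABRV
merged into DIS (7); DIS and ABRV dropped to O (6 — the scheme used by
the extraction pipeline); and additionally ETHN dropped (5). During
merging, a former B-ABRV boundary stays a B- boundary so two adjacent
entities never fuse — this preserves entity counts under entity-level
evaluation. Scheme conversion never increases the number of non-O labels,
and the merged conversion preserves it exactly.

## Preprocessing

Cleaning removes HTML tag remnants, decodes the five standard XML
entities, deletes the stray characters `* ^ $`, and strips commas inside
digit groups ("40,760" → "40760") so numbers survive tokenization.
Stopwords are retained: contextual taggers use them. Sentence splitting
and tokenization are rule-based and offset-preserving (0-based, half-open
character offsets; the convention was an open choice). A repair pass
drops whitespace tokens, re-joins a sentence break that landed inside a
number, and merges thousand-separated digit runs ("1 000 000" → one
token). The merge requires a 1–3-digit head followed by exactly-3-digit
groups separated by single spaces, so genuinely separate numbers such as
"30 4" are never fused. The repair pass is idempotent.

## Weak supervision

Three channels propose spans per sentence:

* **Distant** — longest-match, left-to-right, case-insensitive gazetteer
  lookup (diseases → DIS, locations → LOC, ethnonyms → ETHN, sex terms →
  SEX). Single-token ALL-CAPS gazetteer entries match case-sensitively,
  because abbreviation-like entries ("ChILD") collide with common words
  when case-folded. Demonyms live in the ethnonym gazetteer only.
* **Prescriptive** — declarative token patterns for EPI (modifier\* head
  word, heads: prevalence/incidence/occurrence/frequency, optional
  "rate(s)"/"estimate(s)" tail, plus "incidence/prevalence at birth") and
  STAT (the surface forms `X in Y`, `X/Y`, `X:Y`, `X per Y`,
  `X per million`, `X%`, `X cases`, with optional population-noun tails).
  The rule set ships as a config file (`data/rules.cfg`) so patterns can
  be extended without code changes.
* **Noisy** — a pluggable general-domain NER provider whose
  geopolitical/location, date and nationality types map to LOC, DATE and
  ETHN; all other provider types are discarded, and a failing provider is
  skipped with a warning without affecting the other channels. The
  bundled heuristic provider detects date expressions only ("between 1985
  and 2006", "from X to Y", month-name dates, and years governed by
  in/during/since).

Overlaps are resolved deterministically: prescriptive > distant > noisy,
then longer span, then leftmost. The order reflects precision: task
rules are most specific, dictionaries next, general-domain NER noisiest.
A consequence of the priority rule is that year-like numbers inside an
already-matched STAT span are never re-labelled DATE. Merging is
invariant under permutation of its input. ABRV is never auto-labelled —
it is a manual-annotation class — so weak labels cover seven classes.

## Evaluation

Entity-level evaluation decodes maximal B-/I- runs into spans; a
predicted span is a true positive only when class, start and end all
match a gold span, and denominators are span counts. Token-level
evaluation strips the B-/I- prefix and scores each token independently;
token accuracy (which includes O and compares full tags) is reported
separately. Overall rows at both levels are micro-averages over pooled
counts of the non-O classes; including O would make the overall row
collapse into accuracy. Invalid predicted sequences (I-X after O) are
conservatively repaired to B-X before span extraction. Metrics are kept
at full precision internally and rounded to 3 decimals in reports. The
test suite checks both engines against independent brute-force oracles
(exhaustive span enumeration; scikit-learn's confusion-based scores).

## Taggers and the training harness

Any tagger maps token sequences to IOB2 sequences under a declared
scheme. The reference `RuleTagger` reuses the weak-supervision channels
at inference time and is fully deterministic and download-free; classes
outside its scheme are suppressed.

The fine-tuning harness trains a 2n+1-node softmax token-classification
head with AdamW (decoupled weight decay, linear or cosine schedule,
optional warm-up, inverted dropout on features) in numpy, on top of any
frozen encoder exposing `encode(texts) -> (n, dim)`. The bundled
`HashingEncoder` is a tiny randomly-initialized two-layer encoder over
hashed word identities plus word-shape features — a desk-scale backbone
that makes the harness runnable and testable on CPU in seconds; a
pretrained transformer encoder can be plugged in through the same
interface where available, with `align_labels_to_subwords` handling the
first-subword labelling convention (continuation subwords carry the
ignore marker, and the projection back to word level is lossless for
untruncated sentences).

Default hyperparameters are the reference configuration: 4 epochs,
lr 5e-5, weight decay 0.01, max sequence length 128, batch sizes 16/8,
seed 42, AdamW β=(0.9, 0.99), ε=1e-8, dropout 0.1, init std 0.02. The
`OPTIMIZED_PRESET` carries the grid-search winner (ε=1e-6, warm-up 0.06,
linear schedule) with lr 3e-5 — the grid-consistent value, chosen because
a learning rate below the grid's smallest member by three orders of
magnitude is read as a misprint. Harness smoke conditions used in the
tests: 40 synthetic sentences, 2 epochs, seed 42 (loss decrease), and a
150-epoch memorization run at lr 5e-3 without dropout/decay (capacity
check, token accuracy > 0.95).

## Extraction pipeline

A query (registry ID or name) expands to its full case-folded synonym
list; abstracts come from one or more sources (a JSON-lines fixture store
offline; live clients can implement the same `search` interface) and are
deduplicated by PMID in stable order, capped at a caller-chosen maximum
(no default is asserted — published usage varies between 50 and 500).
Optional filtering drops abstracts without a whole-phrase term match
(STRICT) or without any individual non-stopword term token (LENIENT);
STRICT ⊆ LENIENT ⊆ NONE holds by construction. A small built-in stopword
list keeps LENIENT from matching on "due", "to" and similar tokens of
multi-word disease names.

Study gating applies a pluggable classifier at threshold 0.5; a
probability of exactly 0.5 is retained (only "less than 0.5" is
excluded). The bundled `KeywordESClassifier` is a transparent stand-in:
it counts epidemiology-lexicon hits and maps the count through a logistic
centred at two hits. It is not a trained model and is labelled
accordingly; any classifier implementing `probability(abstract)` can
replace it.

Records carry, per abstract, the gate probability and the EPI/STAT/LOC/
DATE/SEX/ETHN surface strings recovered from the cleaned sentence text by
character offsets, in first-mention order, deduplicated
case-insensitively. Because cleaning strips digit-group commas, extracted
rate strings are comma-free ("1/47000" for an in-text "1/47,000").
Relation extraction is out of scope: co-occurring rates and locations are
reported side by side, not linked.

## Normalization and curated comparison

`parse_rate` recognizes the forms X-in-Y (including "X:Y"), X-per-Y,
slash, percent and per-million, tolerating comma and single-space
thousand separators and ignoring trailing population nouns.
`normalize_per_100k` computes numerator/denominator x 100,000 rounded to
three significant figures — the rounding rule was an open choice, fixed
at three figures because it reproduces all reference normalizations
(2.45, 4, 0.136, 17.1) without over-claiming precision. Normalization is
scale-invariant, idempotent on per-100,000 inputs, and monotone in the
numerator. Records without a location default to "Worldwide" to be
comparable with registry extrapolations.

The comparison filter drops curated rows sourced from expert opinion or
missing a PMID or rate, keeps extraction records with at least one STAT
and at most one identified disease ID, and joins on PMID. Curated range
classes ("1–9/100,000") are compared as opaque strings; when a record
carries several STATs each is normalized independently, since the source
text often gives no basis to choose "the" study rate.

## Synthetic data

The generator emulates the statistical structure of the weakly-labeled
study corpus rather than real PubMed discourse. Defaults: per-class
shares of non-O tokens follow the validated training-set composition
(DIS 49.0%, ABRV 17.5%, STAT 7.9%, LOC 7.4%, EPI 7.2%, DATE 6.4%,
SEX 2.7%, ETHN 1.9%); rates are drawn across the five canonical surface
forms (30/20/20/15/15%); 10% of rates are emitted in a truncated,
denominator-ellipted form flagged as an expected miss, reflecting the
incomplete-form misses the weak labeler is known to make; 3–6 entity
sentences per abstract plus an intro and fillers. A deficit-greedy
scheduler picks each sentence's entity slots toward the target mix, which
empirically lands within ~2 percentage points of target by 300 abstracts.
Rate denominators avoid the 1500–2100 band so they can never be mistaken
for years.

Templates deliberately stay inside the prescriptive rule grammar and the
bundled gazetteers, so on canonical-form output the weak labeler
reproduces the planted gold spans *exactly* over the seven auto-labeled
classes — a hard 1.0 closure oracle, not a soft benchmark. ABRV is
planted in gold (parenthesized initialisms after disease names) but
excluded from the closure comparison since no channel emits it.
Everything is deterministic in (config, seed), with per-abstract seeds
derived as `seed * 1_000_003 + index`.

What passing these tests does **not** show: robustness to real abstract
discourse (anaphora, list constructions, rates split across clauses,
OCR-style noise), to surface forms outside the rule grammar, or to
gazetteer gaps. The truncated-rate channel and the hand-encoded worked
phrases cover a slice of that gap, not all of it.

## Numerical and degenerate-input choices

Percentages in label accounting are rounded half-up to 2 decimals.
Metric denominators of zero yield 0.0 (precision with no predictions,
recall with no gold, F1 at P+R=0). Empty corpora, empty sentences and
all-O inputs are legal everywhere and return empty/zero results. The
train/validation split rounds the hold-out fraction to the nearest
abstract; splitting is unstratified uniform sampling (stratification by
disease was not specified and is not attempted).

## Known limitations

No nested or discontinuous entities; no BIOES schemes; no partial-overlap
evaluation modes or bootstrap confidence intervals; no relation
extraction or coreference; no live API clients or web UI; no Unicode
normalization beyond the five XML entities; word-number rates ("one in
every two million") are not parsed; curated range classes are not
interpreted as intervals; the keyword study-gate is a transparent proxy,
not a trained classifier.
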