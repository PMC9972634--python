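# epiharvest

Epidemiologic-information (EI) extraction tooling for rare-disease
literature: weakly-supervised IOB2 corpus construction, dual-level NER
evaluation, pluggable sequence tagging with a desk-scale fine-tuning
harness, an end-to-end abstract pipeline, and per-100,000 rate
normalization for comparison against curated registry data.

## Who this is for

Curators and researchers who need prevalence/incidence statements —
"a prevalence rate of 1 in 40,760 in North Dakota children" — pulled out
of abstracts as structured records, together with the infrastructure to
build and evaluate the NER models that do the pulling. Everything runs
offline and deterministically.

## The model at its core

Abstracts are tokenized and tagged in the IOB2 scheme over entity classes
for epidemiologic type (EPI), rate (STAT), location (LOC), date (DATE),
sex (SEX), ethnicity/nationality (ETHN), plus disease names (DIS) and
abbreviations (ABRV) in the full corpus scheme. A token classifier over a
scheme of *n* classes needs an output layer of 2*n* + 1 nodes (B-X and
I-X per class, plus O) — 13 nodes for the six-class extraction scheme.

Training corpora are built by weak supervision: **distant** (gazetteer
lookup), **prescriptive** (token-pattern rules for EPI phrases and rate
surface forms like `X in Y`, `X/Y`, `X per million`, `X%`) and **noisy**
(a general-domain NER provider mapped onto LOC/DATE/ETHN) channels,
merged by priority (prescriptive > distant > noisy, then longer, then
leftmost) and emitted as IOB2.

Evaluation is dual-level. Entity level: a predicted span counts only if
class and both boundaries match exactly, with span counts as
denominators. Token level: B-/I- prefixes are stripped and each token is
scored independently, so gold `B-EPI I-EPI I-EPI` against predicted
`B-EPI I-EPI O` gives EPI recall 2/3 at the token level but 0 at the
entity level. Overall rows micro-average pooled counts over non-O
classes; F1 = 2PR/(P+R).

Extracted rates normalize to a common basis as
numerator/denominator × 100,000 to three significant figures
(1 in 40,760 → 2.45 per 100,000), with "Worldwide" assigned when no
location was extracted.

## Worked example

Write the bundled case-study fixtures to disk and run the pipeline for
GRACILE syndrome (registry ID GARD:0000001):

```python
import json, pathlib
from epiharvest.fixtures import case_fixture_abstracts, case_study_dictionary_lines
pathlib.Path("demo").mkdir(exist_ok=True)
with open("demo/abstracts.jsonl", "w") as fh:
    for a in case_fixture_abstracts():
        fh.write(json.dumps({"pmid": a.pmid, "title": a.title, "abstract": a.body}) + "\n")
pathlib.Path("demo/diseases.tsv").write_text("\n".join(case_study_dictionary_lines()) + "\n")
```

```
$ epiharvest extract --disease "GARD:0000001" --source demo/abstracts.jsonl \
      --dictionary demo/diseases.tsv --filter strict --max 500
PMID	Title	EpiProb	EPI	STAT	LOC	DATE	SEX	ETHN
FIX47000	The GRACILE syndrome, a neonatal lethal metabolic disorder with iron overload.	0.731	Incidence	1/47000	Finland			Finnish
```

The query expanded to all eight GRACILE synonyms, three fixture abstracts
were searched, the STRICT filter kept the two mentioning a whole synonym,
and the study gate (probability ≥ 0.5) kept one: an epidemiologic study
reporting an incidence of at least 1/47,000 in Finland, with the Finnish
founder population flagged as ETHN. (Preprocessing strips digit-group
commas, so the in-text "1/47,000" is reported as "1/47000".) The rate
normalizes to a common per-100,000 basis:

```
$ epiharvest normalize "1 in 40,760"
2.45 per 100,000
```

Other entry points: `epiharvest simulate` (synthetic gold-annotated
abstracts), `epiharvest label` (weak supervision → IOB2),
`epiharvest corpus stats|convert|split`, `epiharvest evaluate`
(entity/token reports). Library-level training lives in
`epiharvest.tagger.finetune`; see `docs/methods.md` for the model and its
parameters.

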