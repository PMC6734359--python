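# radphen

Rule-based phenotyping of brain CT/MR radiology reports.

Radiologists' free-text reports are the cheapest large-scale source of brain
imaging phenotypes — infarcts, bleeds, small vessel disease, atrophy,
tumours — but coding tens of thousands of reports by hand is impractical.
`radphen` implements a staged information-extraction pipeline for this
setting, together with the statistics used to validate such systems against
expert annotation, and a synthetic report generator so the whole stack is
testable without access to governance-restricted hospital text.

## What it does

Each report is processed in a fixed stage order:

1. **Zoning** — split the report into *request* (clinical question), *body*
   (findings) and *conclusion* sections via configurable heading regexes.
2. **Tokenisation** — paragraph/sentence/token segmentation protecting
   abbreviations and decimal measurements.
3. **POS tagging** — a coarse 10-tag rule tagger (closed-class word lists plus
   suffix heuristics); any external tagger can be injected through a simple
   contract (surfaces in, equal-length tag list out).
4. **Lemmatisation** — canonical forms (*bleed* for *bled*, *bleeding*,
   *bleeds*) via an exception table and affix rules.
5. **NER** — longest-match lookup over two domain lexicons (disease terms and
   time/location modifiers, ~400 variant entries after hyphenation and ae/e
   spelling expansion), plus prepositional paraphrase patterns such as
   "blood in the subarachnoid spaces".
6. **Negation detection** — pre-triggers ("no", "exclude", "clear of"),
   post-triggers ("unlikely", "not seen"), contrast cues ("rather than"),
   scoped by clause boundaries; hedged possibility ("cannot exclude") is
   flagged *uncertain*, not negated.
7. **Relation extraction** — noun/verb-phrase chunking attaches each
   time/location modifier to at most one disease mention (same noun phrase
   first, then predicative copula, then proximity).
8. **Labelling** — a deterministic mapping from the surviving mark-up to a
   *set* of 24 document-level phenotype labels (e.g. *Ischaemic stroke,
   deep, old*; *Subarachnoid haemorrhage, aneurysmal*; *Tumour, metastasis*).
   Negated and request-section mentions contribute nothing; a stroke mention
   lacking a full (location, time) pair maps to its *underspecified* label.

The evaluation module reports, per phenotype, sensitivity, specificity and
positive predictive value with 95% **Wilson score intervals**

lo, hi = (p̂ + z²/2n ∓ z·√(p̂(1−p̂)/n + z²/4n²)) / (1 + z²/n),

F1 = 2·PPV·sens/(PPV+sens), **Cohen's κ** for document-label agreement,
entity-level precision/recall/F1 (exact-span or overlap matching), and a
Wilson-width **sample-size planner**: the smallest positive-case count whose
interval is narrow enough, scaled by the phenotype prevalence.

## Worked example

```python
from radphen.pipeline import annotate_report
from radphen import evaluation as ev

ann = annotate_report(
    "CLINICAL DETAILS: Sudden onset weakness.\n"
    "REPORT: There is an old left frontal infarct. "
    "There is established small vessel disease. No evidence of acute haemorrhage.\n"
    "CONCLUSION: Old cortical infarct with background small vessel disease.")

for r in ann.relations:
    print(f"{r.kind:<9} {r.modifier.surface!r} -> {r.target.surface!r}")
print(sorted(p.value for p in ann.labelled.labels))
print(ev.wilson_ci(159, 164))
print(ev.min_sample_size(0.95, 0.12, 0.10, round_to=100))
```

prints

```
time      'old' -> 'infarct'
location  'frontal' -> 'infarct'
time      'established' -> 'small vessel disease'
time      'acute' -> 'haemorrhage'
time      'Old' -> 'infarct'
location  'cortical' -> 'infarct'
['Ischaemic stroke, cortical, old', 'Small vessel disease']
(0.9306239840222903, 0.9869085558045885)
700
```

The negated "acute haemorrhage" yields no label (its time relation is
ignored because the target mention is negated); the old frontal/cortical
infarct resolves to one specific stroke label; `wilson_ci(159, 164)` is the
interval around a sensitivity of 159/164, and the planner says 700 reports
are needed to pin a 95% sensitivity at 12% prevalence inside a 10-point
Wilson interval (rounded up to the hundred).

## Command line

```
radphen generate -n 700 -o corpus --seed 1        # synthetic gold corpus
radphen annotate corpus -o out                    # run the pipeline
radphen evaluate out/predictions.jsonl corpus/labels.jsonl   # metrics TSV
radphen stats corpus                              # corpus statistics
```

`generate` writes brat `.txt`/`.ann` pairs, a `labels.jsonl` gold file and
the generating configuration; `evaluate` prints one row per phenotype plus
"any ischaemic stroke", "any haemorrhagic stroke" and "any tumour"
aggregate rows, each with Wilson 95% CIs and F1.

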