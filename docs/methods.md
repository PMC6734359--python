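# Methods

## The extraction model

`radphen` treats phenotype extraction from a radiology report as a pure
function of four layers of mark-up computed in a fixed order: sections,
tokens (with coarse POS tags and lemmas), entities (with negation flags),
and modifier-to-disease relations. The final labelling step consults only
this mark-up, never the raw text, so every label is traceable to the
mentions that produced it (the `provenance` map on a `LabelledReport`).

The design assumption throughout is the one that makes rule-based systems
viable in this domain: radiology prose is topic-focused and highly
conventionalised, so a few hundred lexicon entries and a small set of
trigger/attachment rules cover the bulk of real phrasings, and the dominant
failure mode is *unseen phrasing* rather than ambiguity. The synthetic
corpus makes exactly this failure mode tunable (see below).

## Zoning

Headings are matched case-insensitively at line starts from a configurable
map (defaults: clinical details/history/indication → request;
report/findings → body; conclusion(s)/impression/comment/opinion →
conclusion). Offsets are 0-based half-open after CRLF→LF normalisation.
Choices where the format is underspecified, made once and kept:

- text before any heading is body, unless an explicit body heading exists
  later (then request, if no request heading exists; otherwise it remains
  unassigned inter-section text, like the heading strings themselves);
- a heading kind seen a second time is treated as plain text, since a
  `Section` is a single contiguous span;
- missing sections exist with empty spans so callers iterate uniformly.

Zoning is lossless: section spans never overlap, each section's text equals
the covered substring, and everything not covered is heading/preamble text.

## Tagging and lemmatisation

The built-in tagger is deliberately dependency-free: closed-class word
lists, digit/punctuation classes, `-ly` adverbs, a clinical adjective
suffix set (`-al -ic -ous -ar -oid -ive`), participles resolved by left
context (nominal after a determiner/adjective, verbal otherwise), and a
NOUN default for unknown content words. The downstream rules consult only
the NOUN/VERB/ADJ/ADV/DET distinctions, which is why a coarse 10-tag set
suffices and why any stronger tagger can be injected through the contract
without changing the rest of the system. The lemmatiser combines an
irregular-form table (bled→bleed, metastases→metastasis, ganglia→ganglion,
copulas→be) with affix rules; silent-e restoration consults a small verb
vocabulary (involv→involve) and `-eed` stems are protected (bleed is not a
participle of "ble").

## Lexicon and matching

Lexicon entries are (canonical, entity type, optional tumour/SAH subtype,
variant token sequences). Variant expansion generates, idempotently, the
fused/hyphenated/spaced renderings of the prefixes intra-, extra-, peri-,
sub-, infra-, and ae/e spelling pairs (haemorrhage/hemorrhage), because
clinical dictionaries are dominated by exactly these near-duplicates.
Lookup is longest-match in tokens, left to right, consuming matched tokens
so entities never overlap; ties break by file order. Matching compares both
lemmas and lowercased surfaces on each token, so "microbleeds" reaches a
singular variant and "established" (lemma *establish*) still hits the
surface-form time modifier. The shipped lexicon is a reconstructed starting
vocabulary of standard UK neuroradiology terms covering all 24 labels; it
is a plain TSV and fully overridable, and no claim is made that it matches
any particular production system's vocabulary.

A small pattern set handles prepositional paraphrases the flat scan cannot:
a "blood" mention followed by "in/within the subarachnoid space(s)" is
retyped as subarachnoid haemorrhage with the span widened over the phrase.

## Negation and uncertainty

A disease mention is negated when (a) a pre-trigger (*no, without, absence
of, exclude(s/d), rule(d) out, free of, clear of*) precedes it with no
intervening clause boundary — semicolon, adversative conjunction, or a
comma followed by a finite verb; (b) a post-trigger (*unlikely, less
likely, not seen/identified/demonstrated, is/are excluded*) follows its
noun phrase within the clause; or (c) it falls after a contrast cue
(*rather than*, *as opposed to*), which rejects the second half of the
contrast. Hedged possibility (*cannot exclude X*, *query X*, *?X*,
*possible X*) is deliberately **not** negation: such mentions get a
separate `uncertain` flag which the labeller ignores, treating the finding
as possibly present. Trigger lists, cues and the window are configuration
(YAML-loadable), since no canonical inventory exists for this genre; the
defaults reproduce the documented hard cases ("Exclude subdural bleed.",
"diffusely sclerotic metastases are much less likely", "redistribution of
the original haematoma rather than new blood").

## Relation extraction

Each time/location modifier links to at most one disease mention, by rule
precedence: (a) a disease inside the *same noun phrase* (this dominance is
what stops "new" in "the original haematoma rather than new blood" from
attaching to *haematoma* — it is NP-bound to *blood*); (b) a predicative
modifier after a copula (*the infarct is old*) links to the nearest disease
left of the copula; (c) otherwise the nearest disease within a 5-token
window, unless a contrast cue intervenes; ties prefer the following
mention, matching the dominant "old … infarct" order. The 5-token window is
a configuration default chosen to cover attributive and short predicative
constructions without crossing typical clause widths. One modifier never
links to two conjoined diseases; in coordinations the proximity rule
reaches the shared head noun instead.

## Labelling

Per non-negated disease mention in the body or conclusion: presence
phenotypes (atrophy, small vessel disease, subdural haematoma,
haemorrhagic transformation) label directly; ischaemic/haemorrhagic stroke
mentions with both a location (deep/cortical, the latter rendered "lobar"
for bleeds) and a time (old/recent) relation get the specific grid label,
and otherwise the type's *underspecified* label (the 24-label inventory has
no partially specified cells); an unspecified-stroke mention labels
*Stroke, underspecified*; microbleeds use location only; subarachnoid
haemorrhage is *aneurysmal* when an aneurysm(al) mention shares the
sentence, else *other*; tumours label by lexicon subtype. Labels are a set:
duplicate evidence collapses, and two differently specified mentions of the
same stroke type legitimately emit two labels. Relations into negated
mentions are ignored with a logged warning.

## Evaluation statistics

Report-level confusion counts per phenotype feed sensitivity, specificity
and PPV with 95% Wilson score intervals; the Wilson interval is used
because these proportions sit near 0 or 1, where it remains asymmetric and
well calibrated (the implementation is the closed-form score interval, and
the tests verify it against statsmodels and against numeric inversion of
the score test). Zero-denominator metrics are reported as *undefined*,
never 0; rounding to 2 dp happens only at display time; the small-count
display mask (`--suppress-below`) never affects computation. Cohen's κ uses
product-of-marginals expected agreement with κ=1 for perfect agreement
under degenerate marginals. Entity agreement offers exact-span and
overlap matching (greedy left-to-right, each gold mention matched once)
because annotation-agreement conventions differ on this point; both modes
are first-class. The sample-size planner brackets and bisects on the
strictly decreasing Wilson width; the design (sensitivity 0.95, prevalence
0.12, width 0.10, round up to the hundred) yields m=83 positive cases and
n=700 reports.

## Synthetic corpus

The generator emulates the three-zone structure and findings language of
NHS-style brain imaging reports: per report it samples a label set from
per-phenotype prevalences, realises each label with a findings sentence
(attributive "Old left frontal infarct." or predicative "The frontal
infarct is old.", with laterality decoration), injects negated distractor
sentences ("No evidence of acute haemorrhage.") at a configurable rate,
adds neutral filler sentences, and emits gold entities, relations,
negations and document labels with exact character offsets. Default
prevalences are the regional test-set mix (counts out of 700, with
suppressed small cells instantiated from the gold denominators implied by
the published per-phenotype sensitivities); a routine-practice profile
(atrophy-heavy, vanishingly rare microbleeds, counts out of 110,695) ships
as an alternative. Surface choice respects two stress knobs: `variant_rate`
draws in-lexicon spelling/hyphenation variants, and `paraphrase_rate` draws
out-of-lexicon paraphrases ("area of encephalomalacia"), which degrades
non-negated per-mention recall by approximately the paraphrase rate —
the unseen-phrasing failure mode made measurable. Every generated report
passes a hard self-consistency gate: the labelling rules applied to its own
gold mark-up must reproduce the intended label set exactly.

What the generator does **not** model, and hence what in-lexicon test
results do not show about real reports: free prose style variation between
radiologists and departments, misspellings, cross-sentence coreference,
measurement-laden sentences, mixed-body-region reports, and genuinely novel
phrasings beyond the fixed paraphrase pool. Perfect recovery on generated
text demonstrates internal consistency of the rules, not field performance.

## Problem sizes and determinism

Everything is deterministic given the seed (Python `random.Random`;
reports are generated in a single stream). The test suite exercises the
generator gate at 10,000 reports, end-to-end per-phenotype F1 on a
1,000-report in-lexicon corpus (threshold 0.95), recall degradation at
paraphrase rates 0.3 and 0.6 on 400 reports (tolerance ±0.05), and the
Wilson/score-test equivalence on a 200-point grid — sizes chosen so the
whole suite runs in seconds while keeping binomial noise well inside the
asserted tolerances.

## Known limitations

Sentence structure is not parsed: attachment is chunk- and
proximity-based, so long-range or syntactically inverted modifier
relations can mislink. Negation scope is clause-heuristic, not
constituency-based. The tagger's NOUN default over-accepts unknown words.
Document labels are per report; no per-patient aggregation across serial
scans is attempted. The shipped lexicon is a starting point, not a
validated clinical vocabulary.
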