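# Methods

## Model

`ademiner` treats ADE identification as dictionary lookup followed by
context classification. The unit of analysis is the **mention**: one
occurrence of a lexicon term in one note, with a character span into the
unmodified text. A mention's final status is decided by a deterministic
cascade — eleven removal stages, then retain overrides — and a document or
patient is positive iff it holds at least one positive mention. There is no
learned component; behaviour is fully determined by the term lists, the
stage gazetteers and the window configuration, which makes every decision
auditable (each mention carries the ordered list of rules that fired on it).

Two asymmetries are deliberate and inherited from the design this package
implements:

* **Precision over recall.** Any firing removal stage demotes the mention;
  ambiguous constructions are negative. Missed true mentions are considered
  recoverable because real ADEs tend to be mentioned repeatedly across a
  patient's record.
* **Past events are positive.** "History of dystonia" describes a real
  event; only *no history of* negates. Temporal classification
  (current vs past) is explicitly out of scope.

## Text model and conventions

Offsets are 0-based, half-open, and all modules share them. Tokens are a
partition of the text (word / number / punctuation / symbol / space-run);
`?`, `/`, `@`, `;` are always single-character tokens because one rule
stage tests symbol adjacency. Hyphens are token boundaries, so a two-word
gazetteer entry also matches its hyphenated spelling ("ego dystonic" ↔
"ego-dystonic"). Sentences end at `.`, `!`, `?` or a whitespace run
containing a newline; rule context never crosses a sentence boundary. Case
is preserved in storage and folded at comparison time. De-identification
placeholders (e.g. "ZZZZZ") are ordinary word tokens.

## Rule stages and their scopes

All distances count non-whitespace tokens within the mention's sentence.
"Window" below is the configurable context window, default 5 tokens each
side (`RuleConfig.window_before/window_after`). The default was chosen as
the smallest scope that covers every documented example context; widening
it trades precision for sensitivity to distant cues.

| stage | fires when | scope |
|---|---|---|
| S1 negation-before | `negationbefore` cue before mention | window |
| S2 negation-after | `negationafter` cue after mention | window |
| S3 organisation | `organisation` term adjacent | 1 token |
| S4 symbols | `?` `/` `@` nearest non-space token | adjacent |
| S5 other-person | `people` term anywhere in sentence | sentence |
| S6 monitor | `monitor` cue | window |
| S7 negative-effects | `negseffect` (warning/informing) cue | window |
| S8 single words | "like"/"rates" before; "consider" after | 1 token |
| S9 diagnosis homonym | mention contained in a `diagnost` phrase | containment |
| S10 drug effects | `druglink` (drug-literature) cue | window |
| S11 hypothetical | "if" before; or an `adrin` indication term after | window |
| S12 retain | article/possessive immediately before; diagnostic phrase in window; or patient-reference + indication term in window | see below |

Notes on the genuinely open points and how they were fixed:

* **S1/S2 directionality.** The stage names are read operationally: the
  *cue* precedes (S1) or follows (S2) the ADE term. This is the only
  reading consistent with the documented examples ("did **not** have
  dystonia" → S1).
* **S11.** "Hypothetically discussed" is operationalised as an
  "if"-conditional within the pre-mention window, or an indication term
  (`adrin`: reaction, develops, …) in the post-mention window and outside
  the mention span. Tokens inside the mention never count as cues for any
  stage — otherwise "dystonic **reaction**" would negate itself.
* **S12 retain.** Three sub-rules: (a) "the" or a possessive pronoun as the
  word token immediately before the mention; (b) a diagnostic phrase
  ("diagnosed with", "presented with", …) in window; (c) a
  patient-reference token (patient, pt, he, she — configurable, since
  de-identified text has no names) plus an indication term, both in window.
  "if" is excluded from (c)'s indication terms: it marks hypotheticals.
  Retain precedence over removal is absolute — no weighting.
* **S4 symbol set.** `?`, `/`, `@` only; `;` is tokenised but not a removal
  trigger, since a semicolon most often separates list items that are real
  findings.
* **Evaluation of all stages.** Stages are not short-circuited after the
  first removal; every decision is recorded. This costs a constant factor
  and buys the cumulative ablation report and complete audit trails.

## Gazetteers and lexicons

The nine stage gazetteers plus retain/patient-reference/possessive lists
ship as **starter** lists: each entry is motivated by a documented example
context, not harvested from real records. The same holds for the twelve ADE
lexicons (4 EPSE + 8 non-EPSE). The rule set is ADE-agnostic: adding a new
ADE is adding a lexicon file, no rule changes. Spelling variants are
curated entries (acathisia, akithisia, …); there is deliberately no
automatic edit-distance expansion, which would manufacture false synonyms
("dystonia"/"dystopia"). One conscious interaction: organisation contexts
("the Dystonia Society") can collide with retain rule (a) when "the"
directly precedes the term; since retain precedence is absolute, the
organisation gazetteer is matched adjacently and organisation names
preceded directly by "the" remain a known failure mode documented here
rather than special-cased.

## Evaluation

Mention-level scoring: TP/FP/FN over predicted-positive mentions vs
gold-positive labels, span-matched by **overlap** by default (annotators
classify pre-located term hits; exact-span is available). Undefined ratios
are `None` plus a warning, never 0. The ablation report re-annotates one
fixed corpus per row (keyword-only, then stages cumulatively, then retain);
monotonicity of the positive count down the rows is a structural guarantee,
not an empirical one. Agreement uses the two-rater two-category Cohen's
kappa with marginal-product chance agreement; the implementation is
cross-checked against scikit-learn in the tests.

## Prevalence

Patient flags collapse mentions per (patient, ADE); the roster argument
makes unmentioned patients explicit negatives. Stratified tables cross
flags with an attribute column ("unknown" stratum for missing values).
Pearson X² is computed by direct summation over the strata × {positive,
negative} table with margin-based expectations, **no Yates correction**,
df = (r−1)(c−1); p-values come from the χ² survival function. The shipped
reference table (published cohort sizes and two-decimal percent
prevalences for four EPSEs in 12,879 SMI patients) round-trips exactly:
reconstructing counts as round-half-up(prevalence × cohort) reproduces
every published statistic to 3 decimals and every partition's totals
(390/750/440/324 positives; 12,879 cohort). Half-up rounding and the
absence of a continuity correction were both validated by this round-trip —
banker's rounding or Yates-corrected statistics do not match. One published
value (the age-partition statistic for tardive dyskinesia) duplicates the
akathisia value and recomputes as 134.191; it is excluded from the shipped
reference as a presumed misprint.

## Synthetic corpus generator

The generator emulates the *contextual structure* of mental-health notes,
nothing more: each document is 1–6 sentences, one of which embeds a single
lexicon term in a context family drawn from a configurable mix; the rest
are neutral fillers guaranteed to contain no cues or terms. The default mix
plants 62% positive contexts (plain + retain), matching the positive rate a
bare keyword search typically finds in this kind of text, with negation the
most common negative family. Casing jitter and misspelling variants (at a
default 10% rate) prevent matches from being positional artefacts. Patient
attributes are sampled from the reference cohort's marginal distributions
(8 age bands, 2 genders, 4 ethnic groups, 3 diagnoses) so prevalence
workflows run end to end. Output is fully determined by the spec + seed.

The diagnosis-homonym family is term-specific ("ego dystonia"); when the
target lexicon has no homonym surface, the generator substitutes a
hypothetical-family sentence and records the realised family.

What passing on synthetic corpora does and does not show: every template is
decidable by exactly one rule family, so precision = recall = 1.0 end to
end certifies the rule mechanics (each stage fires on its family and only
its family), and disabling stage *k* flips exactly family *k*'s negatives.
It does **not** estimate real-world performance: real notes contain cue
variants outside the starter gazetteers, long-range context, and ambiguity
with no template analogue. On real corpora, precision/recall depend mostly
on gazetteer curation.

## Problem sizes and numerical choices

Tests and the acceptance script use corpora of 25–400 patients (up to ~1000
documents), the scale at which every behavioural property is already
exercised; the pipeline is linear in corpus size. Chi-square equivalence to
the SciPy oracle is asserted at 1e-9; kappa against scikit-learn at 1e-12;
published statistics at their printed precision (5e-4 for 3-decimal values,
5e-3 where two-decimal prevalence rounding propagates). Ties and degenerate
inputs: empty text yields no tokens and no sentences; a candidate matched
at identical spans by two lexicons is a validation error (ambiguous lexicon
design); zero contingency margins are validation errors rather than NaNs.

## Known limitations

* Starter gazetteers are illustrative; coverage of real cue vocabulary is
  the dominant unmodelled factor.
* Sentence splitting is terminator-based; abbreviations ("Dr. Smith") split
  spuriously, which can only shrink rule scope (never leak context).
* Retain rule (a) fires on any "the" + term bigram, including organisation
  names ("the Dystonia Society") — see above.
* No drug-name linkage, causality, or temporality; document-type-specific
  parsing (letters vs events) is not attempted.
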