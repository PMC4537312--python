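# ademiner

Rule-based extraction of adverse drug event (ADE) mentions from free-text
clinical notes, with mention-level evaluation, inter-annotator agreement,
and stratified patient-level prevalence analysis.

## The problem

Electronic health records in mental healthcare hold most of their clinical
signal in free text. Movement disorders caused by antipsychotics —
extrapyramidal side effects (EPSEs): dystonia, akathisia, Parkinsonism and
tardive dyskinesia — are recorded in running prose, and a bare keyword
search for the terms is badly imprecise: clinicians also write the words
when *negating* them ("denied any dystonic reactions"), *warning* about them
("possibility of dystonia with clozapine"), *monitoring* for them ("check
for any dystonic reaction"), discussing *someone else* ("mother had
developed dystonia"), naming an *organisation* ("Dystonia Society"), or
speaking *hypothetically* ("If dystonia develops give procyclidine dose").

`ademiner` implements the classic dictionary-plus-context-rules design for
this problem, for researchers doing pharmacovigilance on EHR text:

1. **Candidate identification.** Every occurrence of a term from a curated
   ADE lexicon (canonical name, synonyms, misspelling variants such as
   *akithisia* → akathisia) is located case-insensitively on token
   boundaries, longest match first.
2. **Removal cascade.** Eleven ordered rule stages each demote candidates in
   one non-affirming context family (negation before/after, organisation,
   adjacent `?` `/` `@` symbols, other person, monitoring, side-effect
   warning, single context words, diagnostic homonyms like *ego-dystonic*,
   drug-literature context, hypotheticals). Cues come from per-stage
   gazetteers; context never crosses a sentence boundary and most stages
   respect a 5-token window. The cascade favours precision over recall:
   ambiguity means removal.
3. **Retain override.** A definite article or possessive pronoun immediately
   before the term ("her dystonia had become worse"), a diagnostic phrase
   ("diagnosed with"), or a patient reference co-occurring with an
   indication term rescues a removed mention — retain precedence is
   absolute.

A mention is a positive ADE if no removal rule fired or a retain rule
overrode the removal. Evaluation is mention-level, by precision
TP/(TP+FP) and recall TP/(TP+FN) against gold labels, with a cumulative
per-stage ablation report and Cohen's kappa for annotator agreement.
Downstream, mentions collapse to one flag per patient (positive iff ≥ 1
positive mention) and flags cross demographic strata into prevalence tables
tested with the Pearson chi-square statistic, X² = Σ(O−E)²/E without
continuity correction.

Real psychiatric records cannot ship with a package, so a seedable
generator produces notes that reproduce exactly these context families with
gold labels known by construction, and the package ships the published
per-stratum EPSE prevalences of a 12,879-patient serious-mental-illness
cohort so the published chi-square statistics can be recomputed from
printed values.

## A worked example

```
python examples/annotate_worked_examples.py
```

prints, among others:

```
negative  Denied any dystonic reactions.
          -> 'dystonic reactions' status=removed (S1.negation_before)
negative  Check for any dystonic reaction.
          -> 'dystonic reaction' status=removed (S6.monitor)
POSITIVE  Her dystonia had become worse.
          -> 'dystonia' status=candidate (S12.retain_definite_possessive)
POSITIVE  The patient does not think the dystonia was painful.
          -> 'dystonia' status=retained (S1.negation_before, S12.retain_definite_possessive)
```

The last line shows the override at work: negation fires, but the definite
article immediately before the term retains the mention, so it counts as a
real ADE. The ablation example (`python examples/ablation_report.py`) shows
the cascade's signature shape on a synthetic corpus — precision climbing
0.641 → 1.000 as stages are enabled while recall dips to 0.924, with the
retain row recovering recall to 1.000.

Other examples: `prevalence_tables.py` (recomputes the published chi-square
statistics from printed prevalences), `generate_and_evaluate.py` (full
pipeline scoring on generated notes), `patient_prevalence_synthetic.py`
(patient-level stratified prevalence end to end).

## Command line

A thin CLI wraps the library:

```
ademiner generate --seed 5 --out corpus/
ademiner annotate --input corpus/corpus.jsonl --output mentions.jsonl
ademiner annotate --input corpus/corpus.jsonl --stages 1-6 --no-retain --output ablate.jsonl
ademiner evaluate --pred mentions.jsonl --gold corpus/gold.jsonl
ademiner ablation --input corpus/corpus.jsonl --gold corpus/gold.jsonl
ademiner prevalence --annotations mentions.jsonl --patients corpus/patients.csv \
    --stratify gender --ade dystonia
```

Corpora are read as JSON-lines, a directory of `.txt` files, or a minimal
XML dialect; annotations and gold labels are JSON-lines with character
spans; gazetteers and lexicons are one-phrase-per-line `.lst` files
(`#` comments), overridable via YAML manifests.

## Scope and caveats

The shipped gazetteers are starter lists seeded from documented examples;
production use on real records requires locally curated lists, and
realistic precision/recall depend on that curation — the perfect scores on
synthetic corpora certify the rule mechanics, not real-world performance
(see `docs/methods.md`). Drug–ADE causality, temporal ordering of events
and de-identification are out of scope.
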