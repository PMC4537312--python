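"""Seedable synthetic clinical-note generator with gold labels.

Real psychiatric records cannot be redistributed, so every downstream module
is exercised on generated notes that reproduce the *contextual structure* the
rule cascade targets: an ADE term embedded in a plain positive statement, a
retain-cue context, or one of the removal-context families (negation,
monitoring, side-effect warning, other person, organisation name,
hypothetical, diagnostic homonym, adjacent query symbol, drug-literature
listing). Each generated document contains exactly one embedded term with a
known gold label and a record of which rule stage, if any, is expected to
fire on it, so evaluation and ablation behaviour can be checked against
construction-time truth.

The generator makes no attempt at clinical realism beyond cue structure: no
dosing syntax, no letter formatting, filler sentences are neutral and never
contain cue words or ADE terms.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .corpus import Document, GoldLabel, ValidationError, write_documents_jsonl, write_gold_labels
from .gazetteer import AdeLexicon, default_lexicons

__all__ = ["GeneratorSpec", "GeneratedCorpus", "Template", "generate_corpus", "CONTEXT_FAMILIES"]


@dataclass(frozen=True)
class Template:
    """One sentence pattern; ``{term}`` marks where the ADE surface goes."""

    text: str
    family: str
    gold: str  # positive | negative
    expected_stage: int | None = None  # removal stage expected to fire
    expects_retain: bool = False


# Positive share defaults to ~0.62 of mentions (plain + retain), matching the
# positive rate a bare keyword search finds before any context filtering in
# EHR text of this kind; the remainder spreads over the removal families with
# negation the most common.
DEFAULT_CONTEXT_MIX: dict[str, float] = {
    "plain_positive": 0.42,
    "retain_positive": 0.20,
    "negation": 0.12,
    "monitoring": 0.05,
    "warning": 0.06,
    "other_person": 0.04,
    "organisation": 0.02,
    "hypothetical": 0.04,
    "diagnosis_homonym": 0.01,
    "symbol_adjacent": 0.02,
    "drug_listing": 0.02,
}

TEMPLATES: dict[str, list[Template]] = {
    "plain_positive": [
        Template("Patient developed {term} overnight.", "plain_positive", "positive"),
        Template("{term} noted on examination this morning.", "plain_positive", "positive"),
        Template("On review there was marked {term} today.", "plain_positive", "positive"),
        Template("Ongoing {term} affecting daily activities.", "plain_positive", "positive"),
    ],
    "retain_positive": [
        Template("Her {term} had become worse.", "retain_positive", "positive", expects_retain=True),
        Template("His {term} was troubling him at night.", "retain_positive", "positive", expects_retain=True),
        Template(
            "The patient does not think the {term} was painful.",
            "retain_positive",
            "positive",
            expected_stage=1,
            expects_retain=True,
        ),
        Template("Pt presented with {term} last week.", "retain_positive", "positive", expects_retain=True),
        Template("She was diagnosed with {term} in March.", "retain_positive", "positive", expects_retain=True),
    ],
    "negation": [
        Template("She did not have {term}.", "negation", "negative", expected_stage=1),
        Template("He denied any {term} recently.", "negation", "negative", expected_stage=1),
        Template("No evidence of {term} on examination.", "negation", "negative", expected_stage=1),
        Template("{term} was ruled out.", "negation", "negative", expected_stage=2),
        Template("{term} not present on review.", "negation", "negative", expected_stage=2),
    ],
    "monitoring": [
        Template("Continue to check for {term} at each visit.", "monitoring", "negative", expected_stage=6),
        Template("We will monitor for {term} over coming weeks.", "monitoring", "negative", expected_stage=6),
        Template("Staff to observe for {term} on leave days.", "monitoring", "negative", expected_stage=6),
    ],
    "warning": [
        Template("Discussed possibility of {term} with him.", "warning", "negative", expected_stage=7),
        Template("Warned about {term} before starting treatment.", "warning", "negative", expected_stage=7),
        Template("There is a risk of {term} with this medication.", "warning", "negative", expected_stage=7),
    ],
    "other_person": [
        Template("Mother had developed {term} many years ago.", "other_person", "negative", expected_stage=5),
        Template("His brother has {term} and attends another clinic.", "other_person", "negative", expected_stage=5),
        Template("Her sister also has {term} apparently.", "other_person", "negative", expected_stage=5),
    ],
    "organisation": [
        Template(
            "{term} Society has always been a useful resource for patients.",
            "organisation",
            "negative",
            expected_stage=3,
        ),
        Template("She attended a {term} workshop in June.", "organisation", "negative", expected_stage=3),
        Template(
            "Information from a {term} support group was provided.",
            "organisation",
            "negative",
            expected_stage=3,
        ),
    ],
    "hypothetical": [
        Template("If {term} develops give procyclidine dose.", "hypothetical", "negative", expected_stage=11),
        Template("If {term} occurs stop the medication immediately.", "hypothetical", "negative", expected_stage=11),
    ],
    "diagnosis_homonym": [
        Template("These thoughts are ego {term} in nature.", "diagnosis_homonym", "negative", expected_stage=9),
    ],
    "symbol_adjacent": [
        Template("Any new signs of {term}?", "symbol_adjacent", "negative", expected_stage=4),
        Template("EPSE screen noted {term} / tremor query.", "symbol_adjacent", "negative", expected_stage=4),
    ],
    "drug_listing": [
        Template("Patient given a leaflet about {term} today.", "drug_listing", "negative", expected_stage=10),
        Template(
            "{term} is commonly associated with antipsychotic medication.",
            "drug_listing",
            "negative",
            expected_stage=10,
        ),
        Template("Datasheet lists {term} among reported effects.", "drug_listing", "negative", expected_stage=10),
    ],
}

CONTEXT_FAMILIES = tuple(TEMPLATES)

# The diagnostic-homonym family only exists for dystonia ("ego dystonia" /
# "ego dystonic"); surfaces compatible with the shipped diagnost gazetteer.
_HOMONYM_SURFACES = ("dystonia", "dystonic")

_FILLERS = (
    "Seen at clinic today.",
    "Sleep and appetite remain good.",
    "Plan reviewed at ward round.",
    "Attended appointment on time.",
    "Mental state stable overall.",
    "Community visit completed as planned.",
)

# Attribute category frequencies follow the reference SMI cohort marginals.
_ATTRIBUTE_DISTRIBUTIONS: dict[str, list[tuple[str, float]]] = {
    "age_band": [
        ("Under 21", 318), ("21 to 30", 2106), ("31 to 40", 3018), ("41 to 50", 3249),
        ("51 to 60", 2119), ("61 to 70", 1129), ("71 to 80", 677), ("Above 80", 263),
    ],
    "gender": [("Male", 6969), ("Female", 5910)],
    "ethnicity": [("White", 5788), ("Black", 4682), ("Asians", 861), ("Other", 1548)],
    "diagnosis": [("Schizophreniform", 8411), ("Bipolar", 3208), ("Schizoaffective", 1260)],
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Fully determines a synthetic corpus (same spec + seed = same bytes)."""

    n_patients: int = 50
    docs_per_patient: tuple[int, int] = (1, 4)
    ade_ids: tuple[str, ...] = ("dystonia",)
    context_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CONTEXT_MIX))
    misspelling_rate: float = 0.1
    casing_jitter: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.context_mix) - set(TEMPLATES)
        if unknown:
            raise ValidationError(f"unknown context families: {sorted(unknown)}")
        total = sum(self.context_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"context mix proportions must sum to 1, got {total}")
        if self.n_patients < 1 or self.docs_per_patient[0] < 1:
            raise ValidationError("need at least one patient and one document each")


@dataclass
class GeneratedCorpus:
    documents: list[Document]
    gold_labels: list[GoldLabel]
    patient_attributes: pd.DataFrame
    # construction-time bookkeeping, keyed by (doc_id): realised family and
    # the removal stage expected to fire on the embedded mention
    mention_families: dict[str, str]
    expected_stages: dict[str, int | None]
    patient_truth: dict[tuple[str, str], bool]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_documents_jsonl(self.documents, out / "corpus.jsonl")
        write_gold_labels(self.gold_labels, out / "gold.jsonl")
        self.patient_attributes.to_csv(out / "patients.csv", index=False)


def _pick_surface(rng: random.Random, lexicon: AdeLexicon, misspelling_rate: float) -> str:
    canonical = lexicon.ade_id.casefold()
    variants = sorted(t for t in lexicon.terms if t != canonical)
    if variants and rng.random() < misspelling_rate:
        return rng.choice(variants)
    return canonical


def _realise(
    rng: random.Random,
    template: Template,
    lexicon: AdeLexicon,
    spec: GeneratorSpec,
) -> tuple[str, int, str, Template]:
    """Instantiate one target sentence; returns (text, term offset, surface)."""
    if template.family == "diagnosis_homonym":
        surfaces = [s for s in _HOMONYM_SURFACES if s in lexicon.terms]
        if not surfaces:
            # homonym context is term-specific; substitute a hypothetical one
            template = rng.choice(TEMPLATES["hypothetical"])
            return _realise(rng, template, lexicon, spec)
        surface = rng.choice(surfaces)
    else:
        surface = _pick_surface(rng, lexicon, spec.misspelling_rate)
    if rng.random() < spec.casing_jitter:
        surface = surface.capitalize()
    idx = template.text.index("{term}")
    prefix = template.text[:idx]
    if idx == 0:
        surface = surface[0].upper() + surface[1:]
    sentence = prefix + surface + template.text[idx + len("{term}") :]
    return sentence, len(prefix), surface, template


def _sample_attributes(rng: random.Random, patient_ids: Sequence[str]) -> pd.DataFrame:
    rows = []
    for pid in patient_ids:
        row = {"patient_id": pid}
        for attr, cats in _ATTRIBUTE_DISTRIBUTIONS.items():
            labels = [c[0] for c in cats]
            weights = [c[1] for c in cats]
            row[attr] = rng.choices(labels, weights=weights, k=1)[0]
        rows.append(row)
    return pd.DataFrame(rows)


def generate_corpus(
    spec: GeneratorSpec,
    lexicons: Mapping[str, AdeLexicon] | None = None,
) -> GeneratedCorpus:
    """Generate a gold-labelled corpus of 1–6-sentence notes.

    Each document embeds one ADE term drawn from a lexicon, in a context
    sampled from ``spec.context_mix``; gold labels are positive for the plain
    and retain families and negative for every removal family. Deterministic
    for a fixed spec.
    """
    rng = random.Random(spec.seed)
    if lexicons is None:
        lexicons = default_lexicons(spec.ade_ids)
    lex_list = [lexicons[a.replace("_", " ")] if isinstance(lexicons, Mapping) else a for a in spec.ade_ids]

    families = sorted(spec.context_mix)
    weights = [spec.context_mix[f] for f in families]

    documents: list[Document] = []
    gold_labels: list[GoldLabel] = []
    mention_families: dict[str, str] = {}
    expected_stages: dict[str, int | None] = {}
    patient_truth: dict[tuple[str, str], bool] = {}

    patient_ids = [f"p{ i:05d}".replace(" ", "") for i in range(spec.n_patients)]
    doc_counter = 0
    for pid in patient_ids:
        for ade in spec.ade_ids:
            patient_truth[(pid, ade.replace("_", " "))] = False
        n_docs = rng.randint(*spec.docs_per_patient)
        for _ in range(n_docs):
            doc_id = f"d{doc_counter:06d}"
            doc_counter += 1
            lexicon = rng.choice(lex_list)
            family = rng.choices(families, weights=weights, k=1)[0]
            template = rng.choice(TEMPLATES[family])
            sentence, term_off, surface, template = _realise(rng, template, lexicon, spec)

            n_fillers = rng.randint(0, 5)
            fillers = [rng.choice(_FILLERS) for _ in range(n_fillers)]
            pos = rng.randint(0, n_fillers)
            parts = fillers[:pos] + [sentence] + fillers[pos:]
            text = " ".join(parts)
            offset = sum(len(p) + 1 for p in parts[:pos])  # +1 for joining space

            start = offset + term_off
            end = start + len(surface)
            assert text[start:end] == surface
            documents.append(Document(doc_id=doc_id, text=text, patient_id=pid))
            gold_labels.append(
                GoldLabel(doc_id=doc_id, start=start, end=end, ade_id=lexicon.ade_id, label=template.gold)
            )
            mention_families[doc_id] = template.family
            expected_stages[doc_id] = template.expected_stage
            if template.gold == "positive":
                patient_truth[(pid, lexicon.ade_id)] = True

    return GeneratedCorpus(
        documents=documents,
        gold_labels=gold_labels,
        patient_attributes=_sample_attributes(rng, patient_ids),
        mention_families=mention_families,
        expected_stages=expected_stages,
        patient_truth=patient_truth,
    )
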