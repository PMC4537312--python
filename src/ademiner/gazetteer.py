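"""Term dictionaries (gazetteers) and candidate ADE mention detection.

Candidate identification is a dictionary lookup: every surface form in an ADE
lexicon — canonical name, synonyms and curated misspelling variants — is
matched case-insensitively against the note, aligned to token boundaries,
keeping the longest match at each position. Context rules then decide whether
a candidate is a real ADE; this module only locates candidates and loads the
per-stage cue lists the rules consult.

Gazetteer files are UTF-8, one phrase per line, ``#`` comments, blank lines
ignored (the GATE ``.lst`` convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus import Document, Sentence, Token, ValidationError, split_sentences, tokenize

__all__ = [
    "Gazetteer",
    "AdeLexicon",
    "Mention",
    "load_gazetteer",
    "load_lexicon",
    "default_gazetteers",
    "default_lexicons",
    "find_candidate_mentions",
    "STAGE_GAZETTEER_NAMES",
]

# Stage cue lists the rule cascade expects, by conventional name.
STAGE_GAZETTEER_NAMES = (
    "negationbefore",
    "negationafter",
    "organisation",
    "people",
    "monitor",
    "negseffect",
    "diagnost",
    "druglink",
    "adrin",
    "singleword_before",
    "singleword_after",
    "retain_diagnostic",
    "patientref",
    "possessive",
)

CANDIDATE = "candidate"
REMOVED = "removed"
RETAINED = "retained"


def _phrase_words(phrase: str) -> tuple[str, ...]:
    """Casefolded word/number tokens of a phrase; hyphens are boundaries."""
    return tuple(
        t.surface.casefold() for t in tokenize(phrase) if not t.is_space and t.surface != "-"
    )


@dataclass
class Gazetteer:
    """A named list of cue phrases used by one rule stage."""

    name: str
    entries: frozenset[str]
    _phrases: tuple[tuple[str, ...], ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError(f"gazetteer {self.name!r} has no entries")
        self._phrases = tuple(sorted({_phrase_words(e) for e in self.entries}, key=len, reverse=True))

    def phrase_token_sequences(self) -> tuple[tuple[str, ...], ...]:
        return self._phrases

    def __contains__(self, phrase: str) -> bool:
        return phrase.casefold() in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class AdeLexicon:
    """Surface forms for one canonical ADE (adverse drug event).

    ``terms`` include the canonical name itself plus synonyms and alternate
    spellings (e.g. akathisia: acathisia, acasthisia, akithisia); recall of
    the keyword step depends entirely on how rich this list is.
    """

    ade_id: str
    terms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValidationError(f"lexicon {self.ade_id!r} has no terms")
        if self.ade_id.casefold() not in {t.casefold() for t in self.terms} and not any(
            _phrase_words(t) == _phrase_words(self.ade_id) for t in self.terms
        ):
            raise ValidationError(f"lexicon {self.ade_id!r} must contain its canonical name")


@dataclass
class Mention:
    """One candidate ADE term hit and the audit trail of rules applied to it.

    ``status`` transitions candidate→removed (a removal stage fired) and
    removed→retained (a retain rule overrode the removal). ``fired_rules``
    records every stage decision in order, whether or not it changed status.
    """

    doc_id: str
    ade_id: str
    start: int
    end: int
    matched_term: str
    sentence_index: int
    status: str = CANDIDATE
    fired_rules: list[str] = field(default_factory=list)
    patient_id: str | None = None

    @property
    def is_positive(self) -> bool:
        return self.status in (CANDIDATE, RETAINED)


def _read_lst(path: Path) -> frozenset[str]:
    entries = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                entries.add(line.casefold())
    return frozenset(entries)


def load_gazetteer(path: str | Path, name: str | None = None) -> Gazetteer:
    path = Path(path)
    return Gazetteer(name=name or path.stem, entries=_read_lst(path))


def load_lexicon(path: str | Path, ade_id: str | None = None) -> AdeLexicon:
    path = Path(path)
    return AdeLexicon(ade_id=ade_id or path.stem.replace("_", " "), terms=_read_lst(path))


def _data_dir() -> Path:
    return Path(str(resources.files("ademiner").joinpath("data")))


def default_gazetteers() -> dict[str, Gazetteer]:
    """Load the starter stage gazetteers shipped with the package.

    These are deliberately small seed lists covering the cue families the
    rules target; production use on real records needs richer, locally
    curated lists.
    """
    gaz_dir = _data_dir() / "gazetteers"
    return {p.stem: load_gazetteer(p) for p in sorted(gaz_dir.glob("*.lst"))}


def default_lexicons(ade_ids: Sequence[str] | None = None) -> dict[str, AdeLexicon]:
    """Load shipped ADE lexicons (all twelve, or the named subset)."""
    lex_dir = _data_dir() / "lexicons"
    lex = {}
    for p in sorted(lex_dir.glob("*.lst")):
        ade_id = p.stem.replace("_", " ")
        if ade_ids is None or ade_id in ade_ids or p.stem in (ade_ids or ()):
            lex[ade_id] = load_lexicon(p, ade_id=ade_id)
    if ade_ids is not None:
        wanted = {a.replace("_", " ") for a in ade_ids}
        missing = wanted - set(lex)
        if missing:
            raise ValidationError(f"no shipped lexicon for: {sorted(missing)}")
    return lex


def _match_phrase_at(
    words: Sequence[Token], i: int, phrase: tuple[str, ...]
) -> int | None:
    """Try to match ``phrase`` starting at non-space token ``i``.

    Tokens are compared casefolded; intervening '-' tokens are skipped so a
    two-word entry matches its hyphenated spelling. Returns the index of the
    last matched token, or None.
    """
    j = i
    for k, word in enumerate(phrase):
        if k > 0:
            while j < len(words) and words[j].surface == "-":
                j += 1
        if j >= len(words) or words[j].surface.casefold() != word:
            return None
        j += 1
    return j - 1


def find_phrase_occurrences(
    words: Sequence[Token], gazetteer: Gazetteer
) -> list[tuple[int, int, str]]:
    """All occurrences of any gazetteer phrase in a non-space token sequence.

    Returns (first_word_index, last_word_index, matched phrase text) triples;
    overlaps are allowed (context rules only need existence and position).
    """
    hits = []
    for i in range(len(words)):
        for phrase in gazetteer.phrase_token_sequences():
            last = _match_phrase_at(words, i, phrase)
            if last is not None:
                hits.append((i, last, " ".join(phrase)))
    return hits


def find_candidate_mentions(
    document: Document,
    lexicons: Mapping[str, AdeLexicon] | Iterable[AdeLexicon],
    tokens: Sequence[Token] | None = None,
    sentences: Sequence[Sentence] | None = None,
) -> list[Mention]:
    """Locate every lexicon term in the document as a candidate mention.

    Matching is case-insensitive, token-boundary aligned and greedy
    longest-first: if both "dystonic reaction" and "dystonic reactions" are
    entries the plural span wins, and matches never overlap. Two lexicons
    claiming the identical span is a lexicon design error.
    """
    if isinstance(lexicons, Mapping):
        lexicons = list(lexicons.values())
    else:
        lexicons = list(lexicons)
    if not lexicons:
        raise ValidationError("at least one ADE lexicon is required")
    if tokens is None:
        tokens = tokenize(document.text)
    if sentences is None:
        sentences = split_sentences(document.text, tokens)

    # (phrase tokens, ade_id), longest first so greedy scan is longest-match
    term_index: list[tuple[tuple[str, ...], str]] = []
    for lex in lexicons:
        for term in lex.terms:
            term_index.append((_phrase_words(term), lex.ade_id))
    term_index.sort(key=lambda t: len(t[0]), reverse=True)

    words = [t for t in tokens if not t.is_space]
    mentions: list[Mention] = []
    i = 0
    while i < len(words):
        best: tuple[int, str] | None = None  # (last index, ade_id)
        for phrase, ade_id in term_index:
            last = _match_phrase_at(words, i, phrase)
            if last is None:
                continue
            if best is None or last > best[0]:
                best = (last, ade_id)
            elif last == best[0] and ade_id != best[1]:
                span_text = document.text[words[i].start : words[last].end]
                raise ValidationError(
                    f"ambiguous lexicons: {best[1]!r} and {ade_id!r} both match "
                    f"{span_text!r} in doc {document.doc_id}"
                )
        if best is None:
            i += 1
            continue
        last, ade_id = best
        start, end = words[i].start, words[last].end
        sent_idx = next(
            (k for k, s in enumerate(sentences) if s.start <= start < s.end), 0
        )
        mentions.append(
            Mention(
                doc_id=document.doc_id,
                ade_id=ade_id,
                start=start,
                end=end,
                matched_term=document.text[start:end],
                sentence_index=sent_idx,
                patient_id=document.patient_id,
            )
        )
        i = last + 1
    return mentions
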