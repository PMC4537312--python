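"""The remove/retain rule cascade that classifies candidate ADE mentions.

Every candidate located by the gazetteer matcher passes through eleven
removal stages, each targeting one context family in which an ADE term does
not describe an event the patient experienced: negation before/after the
term, organisation names, adjacent query symbols, other-person mentions,
monitoring, side-effect warnings, single context words, diagnostic homonyms,
drug-literature context and hypothetical constructions. A mention removed by
any stage may be rescued by retain rules — a definite article or possessive
pronoun immediately before the term, a diagnostic phrase nearby, or a
patient reference co-occurring with an indication term — which take absolute
precedence over removal.

All stages are evaluated for every mention (not short-circuited) so the
decision list forms a complete audit trail and per-stage ablation reports can
be computed from a single pass. Context is confined to the mention's
sentence; most stages additionally respect a configurable token window each
side of the mention (distances count non-whitespace tokens). The cascade is
deliberately precision-first: an ambiguous construction is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .corpus import Document, Sentence, Token, ValidationError, split_sentences, tokenize
from .gazetteer import (
    CANDIDATE,
    REMOVED,
    RETAINED,
    AdeLexicon,
    Gazetteer,
    Mention,
    default_gazetteers,
    find_candidate_mentions,
    find_phrase_occurrences,
)

__all__ = [
    "RuleConfig",
    "RuleDecision",
    "REMOVAL_STAGE_IDS",
    "RETAIN_RULE_IDS",
    "apply_removal_stages",
    "apply_retain_rules",
    "annotate_document",
    "annotate_corpus",
    "write_annotations",
    "read_annotations",
]

REMOVAL_STAGE_IDS: dict[int, str] = {
    1: "S1.negation_before",
    2: "S2.negation_after",
    3: "S3.organisation",
    4: "S4.symbol_punctuation",
    5: "S5.other_person",
    6: "S6.monitor",
    7: "S7.negative_effects",
    8: "S8.single_word_context",
    9: "S9.diagnosis_homonym",
    10: "S10.drug_effects",
    11: "S11.hypothetical",
}

RETAIN_RULE_IDS = (
    "S12.retain_definite_possessive",
    "S12.retain_diagnostic_phrase",
    "S12.retain_patient_indication",
)

_S4_SYMBOLS = {"?", "/", "@"}


@dataclass(frozen=True)
class RuleConfig:
    """Which stages run and how far context rules look.

    ``window_before``/``window_after`` are maximum distances, in
    non-whitespace tokens within the sentence, between a cue and the mention
    (0 intervening tokens = immediately adjacent counts as distance 1). The
    other-person stage ignores the windows and scans the whole sentence; the
    diagnosis-homonym stage tests phrase containment.
    """

    enabled_removal_stages: tuple[int, ...] = tuple(range(1, 12))
    retain_enabled: bool = True
    window_before: int = 5
    window_after: int = 5

    def __post_init__(self) -> None:
        unknown = [s for s in self.enabled_removal_stages if s not in REMOVAL_STAGE_IDS]
        if unknown:
            raise ValidationError(f"unknown removal stage id(s): {unknown}")
        if list(self.enabled_removal_stages) != sorted(set(self.enabled_removal_stages)):
            raise ValidationError("removal stages must be unique and in ascending order")
        if self.window_before < 1 or self.window_after < 1:
            raise ValidationError("context windows must be >= 1 token")

    @classmethod
    def keyword_only(cls) -> "RuleConfig":
        return cls(enabled_removal_stages=(), retain_enabled=False)

    @classmethod
    def through_stage(cls, k: int, retain: bool = False, **kw) -> "RuleConfig":
        return cls(enabled_removal_stages=tuple(range(1, k + 1)), retain_enabled=retain, **kw)


@dataclass(frozen=True)
class RuleDecision:
    """One rule stage's verdict on one mention."""

    mention: Mention
    action: str  # "none" | "remove" | "retain"
    stage_id: str
    trigger_term: str | None = None

    def __post_init__(self) -> None:
        if self.action != "none" and not self.trigger_term:
            raise ValidationError("a firing decision must carry its trigger term")


class _SentenceContext:
    """Mention-centric view of its sentence: word tokens and index bounds."""

    def __init__(self, mention: Mention, tokens: Sequence[Token], sentences: Sequence[Sentence]):
        sent = sentences[mention.sentence_index]
        self.words = [
            t for t in tokens if not t.is_space and sent.start <= t.start < sent.end
        ]
        self.m0 = next(i for i, t in enumerate(self.words) if t.start >= mention.start)
        self.m1 = max(i for i, t in enumerate(self.words) if t.end <= mention.end and t.start >= mention.start)

    def hits(self, gaz: Gazetteer) -> list[tuple[int, int, str]]:
        return find_phrase_occurrences(self.words, gaz)

    def before_within(self, gaz: Gazetteer, window: int) -> str | None:
        for i, j, phrase in self.hits(gaz):
            if j < self.m0 and (self.m0 - 1 - j) < window:
                return phrase
        return None

    def after_within(self, gaz: Gazetteer, window: int) -> str | None:
        for i, j, phrase in self.hits(gaz):
            if i > self.m1 and (i - self.m1 - 1) < window:
                return phrase
        return None

    def anywhere_outside(self, gaz: Gazetteer) -> str | None:
        for i, j, phrase in self.hits(gaz):
            if j < self.m0 or i > self.m1:
                return phrase
        return None

    def containing(self, gaz: Gazetteer) -> str | None:
        for i, j, phrase in self.hits(gaz):
            if i <= self.m0 and j >= self.m1 and (i < self.m0 or j > self.m1):
                return phrase
        return None

    def word_before(self) -> Token | None:
        return self.words[self.m0 - 1] if self.m0 > 0 else None

    def word_after(self) -> Token | None:
        return self.words[self.m1 + 1] if self.m1 + 1 < len(self.words) else None


def _require(gazetteers: Mapping[str, Gazetteer], name: str) -> Gazetteer:
    try:
        return gazetteers[name]
    except KeyError:
        raise ValidationError(f"rule stage requires missing gazetteer {name!r}") from None


def _stage_trigger(
    stage: int, ctx: _SentenceContext, gaz: Mapping[str, Gazetteer], cfg: RuleConfig
) -> str | None:
    """Return the cue that fires ``stage`` for this mention, if any."""
    wb, wa = cfg.window_before, cfg.window_after
    if stage == 1:
        return ctx.before_within(_require(gaz, "negationbefore"), wb)
    if stage == 2:
        return ctx.after_within(_require(gaz, "negationafter"), wa)
    if stage == 3:
        g = _require(gaz, "organisation")
        return ctx.before_within(g, 1) or ctx.after_within(g, 1)
    if stage == 4:
        for tok in (ctx.word_before(), ctx.word_after()):
            if tok is not None and tok.surface in _S4_SYMBOLS:
                return tok.surface
        return None
    if stage == 5:
        return ctx.anywhere_outside(_require(gaz, "people"))
    if stage == 6:
        g = _require(gaz, "monitor")
        return ctx.before_within(g, wb) or ctx.after_within(g, wa)
    if stage == 7:
        g = _require(gaz, "negseffect")
        return ctx.before_within(g, wb) or ctx.after_within(g, wa)
    if stage == 8:
        before = ctx.before_within(_require(gaz, "singleword_before"), 1)
        after = ctx.after_within(_require(gaz, "singleword_after"), 1)
        return before or after
    if stage == 9:
        return ctx.containing(_require(gaz, "diagnost"))
    if stage == 10:
        g = _require(gaz, "druglink")
        return ctx.before_within(g, wb) or ctx.after_within(g, wa)
    if stage == 11:
        adrin = _require(gaz, "adrin")
        for i, j, phrase in ctx.hits(adrin):
            if phrase == "if" and j < ctx.m0 and (ctx.m0 - 1 - j) < wb:
                return phrase
            if phrase != "if" and i > ctx.m1 and (i - ctx.m1 - 1) < wa:
                return phrase
        return None
    raise ValidationError(f"unknown removal stage {stage}")


def apply_removal_stages(
    mention: Mention,
    document: Document,
    gazetteers: Mapping[str, Gazetteer],
    config: RuleConfig = RuleConfig(),
    tokens: Sequence[Token] | None = None,
    sentences: Sequence[Sentence] | None = None,
) -> list[RuleDecision]:
    """Run every enabled removal stage against a candidate mention.

    Decisions are returned in stage order for all enabled stages (action
    "none" where the stage did not fire); the mention's status becomes
    ``removed`` iff at least one stage fired. Spans are never altered.
    """
    if tokens is None:
        tokens = tokenize(document.text)
    if sentences is None:
        sentences = split_sentences(document.text, tokens)
    ctx = _SentenceContext(mention, tokens, sentences)
    decisions = []
    for stage in config.enabled_removal_stages:
        trigger = _stage_trigger(stage, ctx, gazetteers, config)
        stage_id = REMOVAL_STAGE_IDS[stage]
        if trigger is None:
            decisions.append(RuleDecision(mention, "none", stage_id))
        else:
            decisions.append(RuleDecision(mention, "remove", stage_id, trigger))
    if any(d.action == "remove" for d in decisions):
        mention.status = REMOVED
    for d in decisions:
        if d.action == "remove":
            mention.fired_rules.append(d.stage_id)
    return decisions


def _retain_triggers(
    ctx: _SentenceContext, gaz: Mapping[str, Gazetteer], cfg: RuleConfig
) -> list[tuple[str, str]]:
    triggers: list[tuple[str, str]] = []
    before = ctx.word_before()
    possessive = _require(gaz, "possessive")
    if before is not None and before.surface.casefold() in possessive.entries:
        triggers.append((RETAIN_RULE_IDS[0], before.surface.casefold()))
    g = _require(gaz, "retain_diagnostic")
    cue = ctx.before_within(g, cfg.window_before) or ctx.after_within(g, cfg.window_after)
    if cue is not None:
        triggers.append((RETAIN_RULE_IDS[1], cue))
    patientref = _require(gaz, "patientref")
    adrin = _require(gaz, "adrin")
    pref = ctx.before_within(patientref, cfg.window_before) or ctx.after_within(
        patientref, cfg.window_after
    )
    if pref is not None:
        for i, j, phrase in ctx.hits(adrin):
            if phrase == "if":
                continue  # "if" marks hypotheticals, never an indication of presence
            in_window = (j < ctx.m0 and (ctx.m0 - 1 - j) < cfg.window_before) or (
                i > ctx.m1 and (i - ctx.m1 - 1) < cfg.window_after
            )
            if in_window:
                triggers.append((RETAIN_RULE_IDS[2], f"{pref}+{phrase}"))
                break
    return triggers


def apply_retain_rules(
    mention: Mention,
    document: Document,
    gazetteers: Mapping[str, Gazetteer],
    config: RuleConfig = RuleConfig(),
    tokens: Sequence[Token] | None = None,
    sentences: Sequence[Sentence] | None = None,
) -> list[RuleDecision]:
    """Apply the retain overrides to a candidate or removed mention.

    A removed mention with at least one retain decision becomes ``retained``;
    a still-candidate mention is simply confirmed positive. Retain precedence
    over removal is absolute.
    """
    if tokens is None:
        tokens = tokenize(document.text)
    if sentences is None:
        sentences = split_sentences(document.text, tokens)
    ctx = _SentenceContext(mention, tokens, sentences)
    decisions = [
        RuleDecision(mention, "retain", rule_id, trigger)
        for rule_id, trigger in _retain_triggers(ctx, gazetteers, config)
    ]
    if decisions:
        if mention.status == REMOVED:
            mention.status = RETAINED
        mention.fired_rules.extend(d.stage_id for d in decisions)
    return decisions


def annotate_document(
    document: Document,
    lexicons: Mapping[str, AdeLexicon] | Sequence[AdeLexicon],
    gazetteers: Mapping[str, Gazetteer] | None = None,
    config: RuleConfig = RuleConfig(),
) -> list[Mention]:
    """Full pipeline on one note: candidates, removal stages, retain rules.

    Returns every mention with its final status and rule trail; the positive
    set is the mentions whose status is ``candidate`` or ``retained``.
    Deterministic for fixed inputs.
    """
    if gazetteers is None:
        gazetteers = default_gazetteers()
    tokens = tokenize(document.text)
    sentences = split_sentences(document.text, tokens)
    mentions = find_candidate_mentions(document, lexicons, tokens, sentences)
    for m in mentions:
        apply_removal_stages(m, document, gazetteers, config, tokens, sentences)
        if config.retain_enabled:
            apply_retain_rules(m, document, gazetteers, config, tokens, sentences)
    return mentions


def annotate_corpus(
    documents: Sequence[Document],
    lexicons: Mapping[str, AdeLexicon] | Sequence[AdeLexicon],
    gazetteers: Mapping[str, Gazetteer] | None = None,
    config: RuleConfig = RuleConfig(),
) -> list[Mention]:
    if gazetteers is None:
        gazetteers = default_gazetteers()
    out: list[Mention] = []
    for doc in documents:
        out.extend(annotate_document(doc, lexicons, gazetteers, config))
    return out


def write_annotations(mentions: Sequence[Mention], path) -> None:
    """Write mentions as JSON-lines annotation records."""
    import json

    with open(path, "w", encoding="utf-8") as fh:
        for m in mentions:
            fh.write(
                json.dumps(
                    {
                        "doc_id": m.doc_id,
                        "patient_id": m.patient_id,
                        "ade_id": m.ade_id,
                        "start": m.start,
                        "end": m.end,
                        "matched_term": m.matched_term,
                        "status": m.status,
                        "fired_rules": m.fired_rules,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_annotations(path) -> list[Mention]:
    import json

    mentions = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            mentions.append(
                Mention(
                    doc_id=str(rec["doc_id"]),
                    ade_id=str(rec["ade_id"]),
                    start=int(rec["start"]),
                    end=int(rec["end"]),
                    matched_term=str(rec["matched_term"]),
                    sentence_index=int(rec.get("sentence_index", 0)),
                    status=str(rec["status"]),
                    fired_rules=list(rec.get("fired_rules", [])),
                    patient_id=(str(rec["patient_id"]) if rec.get("patient_id") else None),
                )
            )
    return mentions
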