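"""Run the remove/retain cascade over the canonical worked-example sentences.

Each sentence embeds a dystonia term in a context the rules target: seven
contexts where the mention is not a real adverse drug event (negation,
warning, organisation name, hypothetical, monitoring, other person) and five
where a retain cue confirms it is. The printed status shows which rule fired.
"""

from ademiner import Document, annotate_document, default_gazetteers, default_lexicons

TEXTS = [
    "Did not have dystonia.",
    "Denied any dystonic reactions.",
    "Possibility of dystonia with ZZZZZ.",
    "Dystonia Society have always been a useful resource for patients.",
    "If Dystonia develops give procyclidine dose.",
    "Check for any dystonic reaction.",
    "Mother had developed dystonia many years ago.",
    "Her dystonia had become worse.",
    "His dystonia had become a problem.",
    "Her dystonia was severe.",
    "His dystonia being reduced.",
    "The patient does not think the dystonia was painful.",
]


def main() -> None:
    gazetteers = default_gazetteers()
    lexicons = default_lexicons(["dystonia"])
    for text in TEXTS:
        (m,) = annotate_document(Document("d", text), lexicons, gazetteers)
        verdict = "POSITIVE" if m.is_positive else "negative"
        rules = ", ".join(m.fired_rules) or "no rule fired"
        print(f"{verdict:8s}  {text}")
        print(f"          -> '{m.matched_term}' status={m.status} ({rules})")
    print(
        "\nA mention is a positive ADE when its status is 'candidate' (no removal"
        "\nrule fired) or 'retained' (a retain cue overrode the removal)."
    )


if __name__ == "__main__":
    main()
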