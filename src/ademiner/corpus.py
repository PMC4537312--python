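"""Document model, corpus readers/writers, tokenisation and sentence splitting.

All downstream rule stages operate on character offsets into the raw note
text. Offsets are 0-based and half-open throughout, and the text of a
:class:`Document` is never normalised after load, so every span recorded by
the matcher or a gold annotation can be checked by slicing.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from lxml import etree

__all__ = [
    "Document",
    "Token",
    "Sentence",
    "GoldLabel",
    "ValidationError",
    "read_documents",
    "write_documents_jsonl",
    "tokenize",
    "split_sentences",
    "read_gold_labels",
    "write_gold_labels",
]


class ValidationError(ValueError):
    """Raised when an input record or configuration fails validation."""


@dataclass(frozen=True)
class Document:
    """A single clinical note.

    ``text`` is stored exactly as read; ``meta`` holds free-form string
    metadata such as a date or document type. ``patient_id`` may be ``None``
    for pure-evaluation corpora that carry no patient linkage.
    """

    doc_id: str
    text: str
    patient_id: str | None = None
    meta: Mapping[str, str] = field(default_factory=dict)


# Token kinds. Space runs are kept as tokens so that the token sequence is a
# partition of the text; matching code filters them out where irrelevant.
WORD = "word"
NUMBER = "number"
PUNCTUATION = "punctuation"
SYMBOL = "symbol"
SPACE = "space-run"

_PUNCT_CHARS = set(".,;:!?'\"()[]{}-‘’“”")


@dataclass(frozen=True)
class Token:
    start: int
    end: int
    surface: str
    kind: str

    @property
    def is_space(self) -> bool:
        return self.kind == SPACE


@dataclass(frozen=True)
class Sentence:
    start: int
    end: int


@dataclass(frozen=True)
class GoldLabel:
    """A manually assigned classification for one located ADE term mention."""

    doc_id: str
    start: int
    end: int
    ade_id: str
    label: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative"):
            raise ValidationError(f"gold label must be positive/negative, got {self.label!r}")


_SCANNER = re.compile(
    r"(?P<space>\s+)|(?P<word>[^\W\d_]+)|(?P<number>\d+(?:\.\d+)?)|(?P<other>.)",
    re.UNICODE,
)


def tokenize(text: str) -> list[Token]:
    """Split ``text`` into an ordered, non-overlapping cover of tokens.

    Every character belongs to exactly one token; non-word characters such as
    '?', '/', '@' and ';' become single-character punctuation/symbol tokens so
    that adjacency rules can see them. Hyphens are boundary characters:
    "ego-dystonic" yields three tokens.
    """
    tokens: list[Token] = []
    for m in _SCANNER.finditer(text):
        kind = m.lastgroup
        surface = m.group()
        if kind == "space":
            tok_kind = SPACE
        elif kind == "word":
            tok_kind = WORD
        elif kind == "number":
            tok_kind = NUMBER
        else:
            tok_kind = PUNCTUATION if surface in _PUNCT_CHARS else SYMBOL
        tokens.append(Token(m.start(), m.end(), surface, tok_kind))
    return tokens


_TERMINATORS = {".", "!", "?"}


def split_sentences(text: str, tokens: Sequence[Token]) -> list[Sentence]:
    """Segment ``text`` into sentences covering every token.

    A sentence ends after '.', '!' or '?' (plus any immediately following
    whitespace) or at a whitespace run containing a newline. Context rules
    never look across the boundaries produced here.
    """
    if not tokens:
        return []
    sentences: list[Sentence] = []
    sent_start = tokens[0].start
    i = 0
    n = len(tokens)
    while i < n:
        tok = tokens[i]
        ends = False
        end_at = tok.end
        if tok.surface in _TERMINATORS:
            ends = True
            # attach trailing whitespace to this sentence
            if i + 1 < n and tokens[i + 1].is_space:
                i += 1
                end_at = tokens[i].end
        elif tok.is_space and "\n" in tok.surface:
            ends = True
        if ends:
            sentences.append(Sentence(sent_start, end_at))
            sent_start = tokens[i + 1].start if i + 1 < n else end_at
        i += 1
    if sent_start < tokens[-1].end:
        sentences.append(Sentence(sent_start, tokens[-1].end))
    return sentences


def _doc_from_record(rec: Mapping, index: int) -> Document:
    if "doc_id" not in rec or rec["doc_id"] in (None, ""):
        raise ValidationError(f"record {index} is missing doc_id")
    return Document(
        doc_id=str(rec["doc_id"]),
        text=str(rec.get("text", "")),
        patient_id=(str(rec["patient_id"]) if rec.get("patient_id") not in (None, "") else None),
        meta=dict(rec.get("meta") or {}),
    )


def _read_jsonl(path: Path) -> list[Document]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            docs.append(_doc_from_record(json.loads(line), i))
    return docs


def _read_text_dir(path: Path) -> list[Document]:
    docs = []
    meta_path = path / "metadata.jsonl"
    meta: dict[str, dict] = {}
    if meta_path.exists():
        with open(meta_path, encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    rec = json.loads(line)
                    meta[str(rec["doc_id"])] = rec
    for f in sorted(path.glob("*.txt")):
        doc_id = f.stem
        side = meta.get(doc_id, {})
        docs.append(
            Document(
                doc_id=doc_id,
                text=f.read_text(encoding="utf-8"),
                patient_id=(str(side["patient_id"]) if side.get("patient_id") else None),
                meta=dict(side.get("meta") or {}),
            )
        )
    return docs


def _read_xml(path: Path) -> list[Document]:
    tree = etree.parse(str(path))
    docs = []
    for i, el in enumerate(tree.getroot().iter("doc")):
        doc_id = el.get("id")
        if not doc_id:
            raise ValidationError(f"record {i} is missing doc_id (XML 'id' attribute)")
        text_el = el.find("text")
        docs.append(
            Document(
                doc_id=doc_id,
                text=text_el.text or "" if text_el is not None else "",
                patient_id=el.get("patient") or None,
            )
        )
    return docs


def read_documents(path: str | Path, format: str = "jsonl") -> list[Document]:
    """Read a corpus from ``path``.

    ``format`` is one of ``text-dir`` (one ``.txt`` file per note, filename =
    doc_id, optional ``metadata.jsonl`` sidecar), ``jsonl`` (records with
    ``doc_id``, ``patient_id``, ``text``, ``meta``) or ``xml``
    (``<corpus><doc id="" patient=""><text>...</text></doc></corpus>``).
    Texts are returned exactly as stored; doc_ids must be unique.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")
    if format == "jsonl":
        docs = _read_jsonl(path)
    elif format == "text-dir":
        docs = _read_text_dir(path)
    elif format == "xml":
        docs = _read_xml(path)
    else:
        raise ValidationError(f"unknown corpus format {format!r}")
    seen: set[str] = set()
    for d in docs:
        if d.doc_id in seen:
            raise ValidationError(f"duplicate doc_id {d.doc_id!r} in corpus")
        seen.add(d.doc_id)
    return docs


def write_documents_jsonl(docs: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            rec = {"doc_id": d.doc_id, "patient_id": d.patient_id, "text": d.text}
            if d.meta:
                rec["meta"] = dict(d.meta)
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_gold_labels(path: str | Path) -> list[GoldLabel]:
    labels = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                rec = json.loads(line)
                labels.append(
                    GoldLabel(
                        doc_id=str(rec["doc_id"]),
                        start=int(rec["start"]),
                        end=int(rec["end"]),
                        ade_id=str(rec["ade_id"]),
                        label=str(rec["label"]),
                    )
                )
    return labels


def write_gold_labels(labels: Iterable[GoldLabel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in labels:
            fh.write(
                json.dumps(
                    {
                        "doc_id": g.doc_id,
                        "start": g.start,
                        "end": g.end,
                        "ade_id": g.ade_id,
                        "label": g.label,
                    }
                )
                + "\n"
            )


def iter_sentence_tokens(
    tokens: Sequence[Token], sentences: Sequence[Sentence]
) -> Iterator[tuple[Sentence, list[Token]]]:
    """Yield each sentence with the tokens it contains."""
    ti = 0
    for sent in sentences:
        within: list[Token] = []
        while ti < len(tokens) and tokens[ti].start < sent.end:
            if tokens[ti].start >= sent.start:
                within.append(tokens[ti])
            ti += 1
        yield sent, within
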