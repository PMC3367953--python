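"""Document model: sectioning, sentence segmentation, gene-span attachment.

Coordinates are 0-based half-open character offsets into ``full_text``,
which is the NFC-normalized concatenation of the document sections joined
by single spaces.  Using one global coordinate system keeps sentence ids,
species spans and gene spans directly comparable.

Sentence segmentation is a deterministic rule-based splitter: it breaks on
terminal punctuation followed by whitespace and an uppercase letter or
digit, but never after a single capital initial ("E. coli"), a known
biomedical abbreviation ("et al.", "Fig.", "sp.") or a decimal point.
"""

from __future__ import annotations

import bisect
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from lxml import etree

logger = logging.getLogger(__name__)

SECTION_LABELS = ("title", "abstract", "body")

#: Tokens after which a period does not end a sentence.
ABBREVIATIONS = frozenset(
    """
    al etal fig figs eq eqs ref refs no nos vs cf ca approx
    dr mr mrs ms prof st inc ltd co corp
    sp spp subsp str var cv ser
    i.e e.g viz et
    jan feb mar apr jun jul aug sep sept oct nov dec
    """.split()
)


class DocumentError(ValueError):
    """Malformed input document or inconsistent annotation."""


@dataclass(frozen=True)
class Sentence:
    """A sentence span: 0-based id, half-open offsets, owning section."""

    sid: int
    start: int
    end: int
    section_label: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise DocumentError(f"sentence {self.sid}: start must precede end")
        if self.section_label not in SECTION_LABELS:
            raise DocumentError(f"unknown section label {self.section_label!r}")


@dataclass
class Document:
    """A sectioned, sentence-segmented document with stable offsets."""

    doc_id: str
    sections: list[tuple[str, str]]
    full_text: str
    sentences: list[Sentence] = field(default_factory=list)

    def sentence_at(self, offset: int) -> Optional[Sentence]:
        """Sentence whose span contains ``offset``, or the nearest preceding
        sentence for offsets that fall in inter-sentence whitespace."""
        if not self.sentences or offset < 0 or offset >= len(self.full_text) + 1:
            return None
        starts = [s.start for s in self.sentences]
        idx = bisect.bisect_right(starts, offset) - 1
        if idx < 0:
            return None
        return self.sentences[idx]

    def sentence_text(self, sid: int) -> str:
        sent = self.sentences[sid]
        return self.full_text[sent.start:sent.end]

    def section_text(self, label: str) -> str:
        return " ".join(text for lab, text in self.sections if lab == label)


@dataclass(frozen=True)
class GeneMention:
    """A pre-tagged gene span (gene NER is an upstream, external step)."""

    start: int
    end: int
    surface: str
    sid: int


_SENT_BOUNDARY = re.compile(r"[.!?]+")


def _split_sentences(text: str) -> list[tuple[int, int]]:
    """Offsets of sentence spans within ``text`` (local coordinates)."""
    spans: list[tuple[int, int]] = []
    start = 0
    n = len(text)
    for m in _SENT_BOUNDARY.finditer(text):
        end = m.end()
        if end >= n:
            break  # terminal punctuation at text end closes the last span
        # must be followed by whitespace then an uppercase letter, digit or quote
        after = text[end:]
        follow = after.lstrip()
        if after == follow:  # no whitespace after the punctuation
            continue
        if not follow or not (follow[0].isupper() or follow[0].isdigit() or follow[0] in "\"'("):
            continue
        if "." in m.group():
            word = _word_before(text, m.start())
            if _is_abbreviation(word):
                continue
            # decimal such as "3.16" never reaches here (no whitespace after)
        spans.append((start, end))
        start = end + (len(after) - len(follow))
    if start < n:
        # trailing sentence (with or without terminal punctuation)
        tail = text[start:]
        if tail.strip():
            spans.append((start, start + len(tail.rstrip())))
    return [(s + _lead_ws(text, s), e) for s, e in spans]


def _lead_ws(text: str, start: int) -> int:
    i = start
    while i < len(text) and text[i].isspace():
        i += 1
    return i - start


def _word_before(text: str, pos: int) -> str:
    i = pos
    while i > 0 and not text[i - 1].isspace():
        i -= 1
    return text[i:pos]


def _is_abbreviation(word: str) -> bool:
    if not word:
        return True
    # single capital initial: "E." in "E. coli", middle initials in names
    if len(word) == 1 and word.isalpha() and word.isupper():
        return True
    low = word.lower().strip("([{")
    return low in ABBREVIATIONS or low.rstrip(".") in ABBREVIATIONS


def segment_document(raw: str, fmt: str = "text", doc_id: str = "doc") -> Document:
    """Parse and sentence-segment one document.

    ``fmt='text'``: the first non-empty line is the title, the remainder the
    abstract (single-line inputs become title-only documents).
    ``fmt='xml'``: accepts a ``<document><id/><title/><abstract/></document>``
    dialect or PubMed-style ``<ArticleTitle>``/``<AbstractText>`` elements.
    """
    if fmt == "text":
        if not raw.strip():
            raise DocumentError("empty text document")
        sections = _sections_from_text(raw)
    elif fmt == "xml":
        doc_id, sections = _sections_from_xml(raw, doc_id)
    else:
        raise DocumentError(f"unknown format {fmt!r}")
    return build_document(doc_id, sections)


def build_document(doc_id: str, sections: Sequence[tuple[str, str]]) -> Document:
    """Assemble a Document from (label, text) sections and segment it."""
    clean = [
        (label, unicodedata.normalize("NFC", text).strip())
        for label, text in sections
        if text and text.strip()
    ]
    for label, _ in clean:
        if label not in SECTION_LABELS:
            raise DocumentError(f"unknown section label {label!r}")
    if not clean:
        raise DocumentError(f"document {doc_id!r} has no non-empty sections")
    full_text = " ".join(text for _, text in clean)
    sentences: list[Sentence] = []
    offset = 0
    for label, text in clean:
        for s, e in _split_sentences(text):
            sentences.append(
                Sentence(sid=len(sentences), start=offset + s, end=offset + e,
                         section_label=label)
            )
        offset += len(text) + 1  # single-space joiner
    return Document(doc_id=doc_id, sections=clean, full_text=full_text,
                    sentences=sentences)


def _sections_from_text(raw: str) -> list[tuple[str, str]]:
    lines = [ln for ln in raw.splitlines() if ln.strip()]
    if len(lines) <= 1:
        return [("title", raw.strip())]
    return [("title", lines[0].strip()), ("abstract", " ".join(ln.strip() for ln in lines[1:]))]


def _sections_from_xml(raw: str, doc_id: str) -> tuple[str, list[tuple[str, str]]]:
    try:
        root = etree.fromstring(raw.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise DocumentError(f"malformed XML: {exc}") from exc

    def first_text(*tags: str) -> Optional[str]:
        for tag in tags:
            el = root.find(f".//{tag}")
            if el is not None and el.text and el.text.strip():
                return el.text.strip()
        return None

    found_id = first_text("id", "PMID")
    title = first_text("title", "ArticleTitle")
    abstract = first_text("abstract", "AbstractText")
    body = first_text("body")
    if title is None and abstract is None and body is None:
        raise DocumentError(
            f"XML document {doc_id!r}: no <title>/<ArticleTitle>, "
            f"<abstract>/<AbstractText> or <body> element found"
        )
    sections = []
    if title:
        sections.append(("title", title))
    if abstract:
        sections.append(("abstract", abstract))
    if body:
        sections.append(("body", body))
    return (found_id or doc_id), sections


def attach_gene_mentions(
    doc: Document, spans: Iterable[tuple[int, int]]
) -> list[GeneMention]:
    """Resolve raw (start, end) gene spans against a document.

    Each span gets its surface text and the id of the sentence containing
    its start.  Spans crossing a sentence boundary keep the start sentence
    (with a warning); degenerate or out-of-bounds spans are an error.
    """
    genes: list[GeneMention] = []
    n = len(doc.full_text)
    for start, end in spans:
        if start >= end:
            raise DocumentError(f"degenerate gene span ({start}, {end})")
        if start < 0 or end > n:
            raise DocumentError(
                f"gene span ({start}, {end}) out of bounds for document "
                f"{doc.doc_id!r} of length {n}"
            )
        sent = doc.sentence_at(start)
        if sent is None:
            raise DocumentError(
                f"gene span ({start}, {end}) not inside any sentence of "
                f"{doc.doc_id!r}"
            )
        if end > sent.end:
            logger.warning(
                "gene span (%d, %d) in %s crosses a sentence boundary; "
                "assigned to sentence %d", start, end, doc.doc_id, sent.sid,
            )
        genes.append(GeneMention(start=start, end=end,
                                 surface=doc.full_text[start:end], sid=sent.sid))
    return genes
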