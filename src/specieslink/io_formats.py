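"""Readers and writers for corpora, annotations and gold standards.

Supported inputs: directories of plain-text or XML documents and
PubTator-style files (``pmid|t|title`` / ``pmid|a|abstract`` blocks with
tab-separated annotation lines).  Outputs: a small versioned XML dialect
that records per-sentence ids and per-mention start/end/tax_id, and a flat
TSV; both round-trip losslessly through the matching readers.

Gold standards for assignment evaluation use one canonical TSV dialect:
``doc_id<TAB>start<TAB>end<TAB>surface<TAB>tax_id``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from lxml import etree

from specieslink.assign import Assignment
from specieslink.preprocess import (
    Document,
    DocumentError,
    GeneMention,
    build_document,
    segment_document,
)
from specieslink.recognize import SpeciesMention

logger = logging.getLogger(__name__)

ANNOTATION_XML_VERSION = "1.0"


@dataclass(frozen=True)
class GoldRecord:
    """A hand-tagged gene span with its gold species id."""

    doc_id: str
    start: int
    end: int
    surface: str
    tax_id: int


@dataclass
class CorpusReadReport:
    """Documents read plus per-file failures (collected, not fatal)."""

    documents: list[Document] = field(default_factory=list)
    failures: list[tuple[str, str]] = field(default_factory=list)


def read_corpus(path: str | Path, fmt: str = "text_dir") -> CorpusReadReport:
    """Read a corpus; per-file parse errors are collected and reported.

    ``text_dir``/``xml_dir`` read ``*.txt``/``*.xml`` files from a
    directory (doc_id = file stem unless the XML declares one); ``pubtator``
    reads a single multi-document file.  Raises if the path is unreadable
    or if no document parses at all.  Output is ordered by doc_id.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"corpus path does not exist: {p}")
    report = CorpusReadReport()
    if fmt == "pubtator":
        docs, anns = read_pubtator(p)
        report.documents = docs
    elif fmt in ("text_dir", "xml_dir"):
        ext, parse_fmt = (".txt", "text") if fmt == "text_dir" else (".xml", "xml")
        files = sorted(f for f in p.iterdir() if f.suffix == ext)
        for f in files:
            try:
                doc = segment_document(f.read_text(encoding="utf-8"),
                                       fmt=parse_fmt, doc_id=f.stem)
                report.documents.append(doc)
            except (DocumentError, UnicodeDecodeError) as exc:
                logger.error("failed to parse %s: %s", f, exc)
                report.failures.append((str(f), str(exc)))
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")
    if not report.documents:
        raise DocumentError(f"no parsable documents found under {p}")
    report.documents.sort(key=lambda d: d.doc_id)
    return report


# ---------------------------------------------------------------------------
# PubTator format.

def read_pubtator(
    path: str | Path,
) -> tuple[list[Document], dict[str, list[tuple[int, int, str, str, Optional[str]]]]]:
    """Parse a PubTator file.

    Returns documents and, per doc_id, annotation tuples
    ``(start, end, text, type, id-or-None)``.  Offsets are taken verbatim
    (PubTator's convention -- title then abstract joined by one separator --
    matches this package's title+space+abstract coordinates).
    """
    docs: list[Document] = []
    annotations: dict[str, list[tuple[int, int, str, str, Optional[str]]]] = {}
    title: Optional[str] = None
    abstract: Optional[str] = None
    doc_id: Optional[str] = None

    def flush() -> None:
        nonlocal title, abstract, doc_id
        if doc_id is not None and (title or abstract):
            sections = []
            if title:
                sections.append(("title", title))
            if abstract:
                sections.append(("abstract", abstract))
            docs.append(build_document(doc_id, sections))
        title = abstract = doc_id = None

    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            flush()
            continue
        if "|t|" in line:
            flush()
            doc_id, _, title = line.partition("|t|")
        elif "|a|" in line:
            did, _, abstract = line.partition("|a|")
            if doc_id is None:
                doc_id = did
        else:
            parts = line.split("\t")
            if len(parts) >= 5:
                did, start, end, text, ann_type = parts[:5]
                ann_id = parts[5] if len(parts) > 5 else None
                annotations.setdefault(did, []).append(
                    (int(start), int(end), text, ann_type, ann_id)
                )
    flush()
    return docs, annotations


def read_gene_spans(
    path: str | Path, annotation_type: str = "Gene"
) -> dict[str, list[tuple[int, int]]]:
    """Read PubTator-style gene annotation lines.

    Accepts both bare TSV lines (``doc_id  start  end  text  Gene [id]``)
    and full PubTator files (title/abstract lines are skipped).
    """
    spans: dict[str, list[tuple[int, int]]] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip() or "|t|" in line or "|a|" in line:
            continue
        parts = line.split("\t")
        if len(parts) < 5:
            raise DocumentError(f"{path}:{lineno}: expected >= 5 tab-separated fields")
        if parts[4] != annotation_type:
            continue
        spans.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    return spans


# ---------------------------------------------------------------------------
# Annotation output (XML and TSV), round-trip safe.

def write_annotations(
    doc: Document,
    mentions: Sequence[SpeciesMention],
    assignments: Sequence[Assignment],
    fmt: str = "xml",
) -> str:
    """Serialize one document's annotations; validates consistency first.

    The XML dialect emits each sentence with its ``sid``/``start``/``end``,
    each species mention and each gene assignment with offsets and tax_id.
    The TSV emits one row per annotation.  Both are parseable by the
    matching readers and byte-stable under write-read-write.
    """
    _validate_annotations(doc, mentions, assignments)
    if fmt == "xml":
        return _write_xml(doc, mentions, assignments)
    if fmt == "tsv":
        return _write_tsv(doc, mentions, assignments)
    raise ValueError(f"unknown output format {fmt!r}")


def _validate_annotations(
    doc: Document,
    mentions: Sequence[SpeciesMention],
    assignments: Sequence[Assignment],
) -> None:
    n = len(doc.full_text)
    for m in mentions:
        if not (0 <= m.start < m.end <= n):
            raise DocumentError(f"species span ({m.start}, {m.end}) out of bounds")
        if doc.full_text[m.start:m.end] != m.surface:
            raise DocumentError(
                f"species surface {m.surface!r} does not match text slice "
                f"{doc.full_text[m.start:m.end]!r}"
            )
    for a in assignments:
        g = a.gene
        if not (0 <= g.start < g.end <= n) or doc.full_text[g.start:g.end] != g.surface:
            raise DocumentError(
                f"gene annotation ({g.start}, {g.end}, {g.surface!r}) is "
                f"inconsistent with document {doc.doc_id!r}"
            )


def _write_xml(
    doc: Document,
    mentions: Sequence[SpeciesMention],
    assignments: Sequence[Assignment],
) -> str:
    root = etree.Element("document", id=doc.doc_id, version=ANNOTATION_XML_VERSION)
    text_el = etree.SubElement(root, "text")
    text_el.text = doc.full_text
    sents_el = etree.SubElement(root, "sentences")
    for s in doc.sentences:
        etree.SubElement(sents_el, "sentence", sid=str(s.sid), start=str(s.start),
                         end=str(s.end), section=s.section_label)
    sp_el = etree.SubElement(root, "species")
    for m in sorted(mentions, key=lambda m: (m.start, m.end)):
        el = etree.SubElement(sp_el, "mention", start=str(m.start), end=str(m.end),
                              tax_id=str(m.tax_id), sid=str(m.sid),
                              provenance=m.provenance)
        el.text = m.surface
    genes_el = etree.SubElement(root, "genes")
    for a in sorted(assignments, key=lambda a: (a.gene.start, a.gene.end)):
        attrs = {"start": str(a.gene.start), "end": str(a.gene.end),
                 "sid": str(a.gene.sid), "rule": a.rule}
        if a.tax_id is not None:
            attrs["tax_id"] = str(a.tax_id)
        el = etree.SubElement(genes_el, "gene", **attrs)
        el.text = a.gene.surface
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def _write_tsv(
    doc: Document,
    mentions: Sequence[SpeciesMention],
    assignments: Sequence[Assignment],
) -> str:
    rows = []
    for m in sorted(mentions, key=lambda m: (m.start, m.end)):
        rows.append(f"{doc.doc_id}\t{m.start}\t{m.end}\t{m.surface}\t"
                    f"Species\t{m.tax_id}\t{m.provenance}")
    for a in sorted(assignments, key=lambda a: (a.gene.start, a.gene.end)):
        tax = "" if a.tax_id is None else str(a.tax_id)
        rows.append(f"{doc.doc_id}\t{a.gene.start}\t{a.gene.end}\t"
                    f"{a.gene.surface}\tGene\t{tax}\t{a.rule}")
    return "\n".join(rows) + ("\n" if rows else "")


def read_annotations_xml(
    xml: str,
) -> tuple[Document, list[SpeciesMention], list[Assignment]]:
    """Parse the XML annotation dialect back into package objects."""
    try:
        root = etree.fromstring(xml.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise DocumentError(f"malformed annotation XML: {exc}") from exc
    from specieslink.preprocess import Sentence  # local to avoid cycle noise

    full_text = root.findtext("text") or ""
    sentences = [
        Sentence(sid=int(s.get("sid")), start=int(s.get("start")),
                 end=int(s.get("end")), section_label=s.get("section"))
        for s in root.findall("sentences/sentence")
    ]
    doc = Document(doc_id=root.get("id"), sections=[], full_text=full_text,
                   sentences=sentences)
    mentions = [
        SpeciesMention(start=int(m.get("start")), end=int(m.get("end")),
                       surface=m.text or "", tax_id=int(m.get("tax_id")),
                       provenance=m.get("provenance"), sid=int(m.get("sid")))
        for m in root.findall("species/mention")
    ]
    assignments = []
    for g in root.findall("genes/gene"):
        gene = GeneMention(start=int(g.get("start")), end=int(g.get("end")),
                           surface=g.text or "", sid=int(g.get("sid")))
        tax = g.get("tax_id")
        assignments.append(Assignment(gene=gene,
                                      tax_id=int(tax) if tax else None,
                                      rule=g.get("rule")))
    return doc, mentions, assignments


def read_annotations_tsv(
    tsv: str,
) -> tuple[list[SpeciesMention], list[Assignment]]:
    """Parse the TSV annotation dialect (mentions carry sid -1: the flat
    format does not serialize sentence structure)."""
    mentions: list[SpeciesMention] = []
    assignments: list[Assignment] = []
    for lineno, line in enumerate(tsv.splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 7:
            raise DocumentError(f"annotation TSV line {lineno}: expected 7 fields")
        _, start, end, surface, kind, tax, extra = parts
        if kind == "Species":
            mentions.append(SpeciesMention(start=int(start), end=int(end),
                                           surface=surface, tax_id=int(tax),
                                           provenance=extra, sid=-1))
        elif kind == "Gene":
            gene = GeneMention(start=int(start), end=int(end),
                               surface=surface, sid=-1)
            assignments.append(Assignment(gene=gene,
                                          tax_id=int(tax) if tax else None,
                                          rule=extra))
        else:
            raise DocumentError(f"annotation TSV line {lineno}: unknown kind {kind!r}")
    return mentions, assignments


# ---------------------------------------------------------------------------
# Gold standard TSV.

@dataclass
class GoldReadReport:
    records: list[GoldRecord] = field(default_factory=list)
    skipped: int = 0


def read_gold(
    path: str | Path, documents: Optional[Mapping[str, Document]] = None
) -> GoldReadReport:
    """Read gold gene-species records from the canonical TSV dialect.

    Lines with non-integer offsets or tax_ids are skipped and counted.
    When ``documents`` is given, a surface mismatch against the document
    text is a warning and the record is kept.
    """
    report = GoldReadReport()
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            logger.error("%s:%d: expected 5 fields, got %d", path, lineno, len(parts))
            report.skipped += 1
            continue
        doc_id, start_s, end_s, surface, tax_s = parts
        try:
            start, end, tax_id = int(start_s), int(end_s), int(tax_s)
        except ValueError:
            logger.error("%s:%d: non-integer offset or tax_id", path, lineno)
            report.skipped += 1
            continue
        if documents is not None and doc_id in documents:
            text = documents[doc_id].full_text
            if text[start:end] != surface:
                logger.warning(
                    "%s:%d: surface %r does not match document slice %r",
                    path, lineno, surface, text[start:end],
                )
        report.records.append(GoldRecord(doc_id=doc_id, start=start, end=end,
                                         surface=surface, tax_id=tax_id))
    return report


def write_gold(records: Iterable[GoldRecord], path: str | Path) -> None:
    lines = [
        f"{r.doc_id}\t{r.start}\t{r.end}\t{r.surface}\t{r.tax_id}"
        for r in records
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
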