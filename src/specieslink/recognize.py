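"""Species mention detection and within-document disambiguation.

Detection is dictionary lookup: every lexicon name is compiled into one
case-insensitive regular expression alternation, anchored at token
boundaries (a match may not be flanked by a letter or digit; hyphens and
periods are legal inside names, so "E. coli K-12" is a single mention).
Overlaps resolve leftmost-longest.

Two refinements run after raw lookup:

* the cell-name rule: a known cell-line name ("HeLa") implies its organism
  when the word "cell"/"cells" co-occurs in the same approximated noun
  phrase (a short right-window of non-function words);
* specificity inference: a general organism term ("Arabidopsis") that
  co-occurs in the document with a specific name ("Arabidopsis thaliana")
  is re-labeled with the specific taxon's id.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

from specieslink.lexicon import CellLineLexicon, SpeciesLexicon, normalize_name
from specieslink.preprocess import Document

PROVENANCES = ("dictionary", "cell_line", "specificity_inferred")

#: Function words that break the approximated noun phrase of the cell rule.
_PHRASE_STOPWORDS = frozenset(
    """
    a an the and or but of in on at to for with by from as that this these
    those was were is are be been being have has had do does did will would
    can could may might shall should must not no nor which who whom whose
    when where while if then than so because although though after before
    during between into through over under it its we our they their he she
    """.split()
)

_CELL_WINDOW = 4  # max tokens between a cell-line name and "cell(s)"


@dataclass(frozen=True)
class SpeciesMention:
    """An organism mention: span, taxonomy id and how it was derived."""

    start: int
    end: int
    surface: str
    tax_id: int
    provenance: str
    sid: int

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")


def _compile_matcher(names: Iterable[str]) -> Optional[re.Pattern]:
    """One alternation over all names; longest-first so the regex engine's
    leftmost-first semantics realize leftmost-longest matching."""
    alts = sorted(set(names), key=lambda n: (-len(n), n))
    if not alts:
        return None
    parts = []
    for name in alts:
        # whitespace in normalized names matches any whitespace run in text
        parts.append(r"\s+".join(re.escape(tok) for tok in name.split(" ")))
    pattern = r"(?<![A-Za-z0-9])(?:" + "|".join(parts) + r")(?![A-Za-z0-9])"
    return re.compile(pattern, re.IGNORECASE)


def detect_species_mentions(
    doc: Document, lex: SpeciesLexicon
) -> list[SpeciesMention]:
    """Dictionary lookup of species names over the whole document.

    Case-insensitive, token-boundary anchored; overlapping candidates are
    resolved leftmost-longest; the result is sorted by start offset.
    """
    matcher = _compile_matcher(lex.entries)
    if matcher is None:
        return []
    mentions: list[SpeciesMention] = []
    for m in matcher.finditer(doc.full_text):
        surface = m.group()
        tax_id = lex.entries[normalize_name(surface)]
        sent = doc.sentence_at(m.start())
        mentions.append(
            SpeciesMention(start=m.start(), end=m.end(), surface=surface,
                           tax_id=tax_id, provenance="dictionary",
                           sid=sent.sid if sent else -1)
        )
    return mentions


_TOKEN = re.compile(r"\S+")


def detect_cell_line_species(
    doc: Document, cells: CellLineLexicon
) -> list[SpeciesMention]:
    """Infer organism mentions from cell-line names (the cell-name rule).

    A cell-line name yields a mention (provenance ``cell_line``, span over
    the name only) iff the token "cell" or "cells" occurs after it within
    the same sentence, at most 4 tokens away, with every intervening token
    a plain content word (no function words, no punctuation except hyphen).
    "HeLa cells" and "HeLa cancer cell" both fire; "HeLa was cultured. The
    cells grew." does not.
    """
    matcher = _compile_matcher(cells.entries)
    if matcher is None:
        return []
    mentions: list[SpeciesMention] = []
    for m in matcher.finditer(doc.full_text):
        sent = doc.sentence_at(m.start())
        if sent is None or m.end() > sent.end:
            continue
        window = doc.full_text[m.end():sent.end]
        if _cell_word_in_phrase(window):
            tax_id = cells.entries[normalize_name(m.group())]
            mentions.append(
                SpeciesMention(start=m.start(), end=m.end(), surface=m.group(),
                               tax_id=tax_id, provenance="cell_line",
                               sid=sent.sid)
            )
    return mentions


def _cell_word_in_phrase(window: str) -> bool:
    tokens = _TOKEN.findall(window)[: _CELL_WINDOW + 1]
    for i, tok in enumerate(tokens):
        if i > _CELL_WINDOW:
            break
        core = tok.strip(".,;:!?)('\"").lower()
        if core in ("cell", "cells"):
            return True
        # intervening token must be a content word: alphabetic with optional
        # internal hyphens, and not a function word
        if not re.fullmatch(r"[A-Za-z]+(?:-[A-Za-z]+)*", tok):
            return False
        if core in _PHRASE_STOPWORDS:
            return False
    return False


def infer_specific_species(
    mentions: Sequence[SpeciesMention],
    hierarchy: Optional[Mapping[int, int]] = None,
) -> list[SpeciesMention]:
    """Re-label general organism terms with a co-occurring specific taxon.

    Scope is document-wide.  A mention is "general" relative to another if
    its tax_id is a proper ancestor of the other's in ``hierarchy``; when no
    hierarchy is supplied, a name-prefix heuristic is used instead ("X" is
    general for "X y...").  Among several specific descendants the
    most-mentioned wins, then the earliest first occurrence.  Spans never
    change, only tax_id and provenance; the operation is idempotent.
    """
    mentions = list(mentions)
    if not mentions:
        return mentions

    counts: dict[int, int] = {}
    first_pos: dict[int, int] = {}
    for m in mentions:
        counts[m.tax_id] = counts.get(m.tax_id, 0) + 1
        first_pos.setdefault(m.tax_id, m.start)

    def descendants_of(general: SpeciesMention) -> set[int]:
        out: set[int] = set()
        for other in mentions:
            if other.tax_id == general.tax_id:
                continue
            if hierarchy is not None:
                if _is_ancestor(general.tax_id, other.tax_id, hierarchy):
                    out.add(other.tax_id)
            else:
                gname = normalize_name(general.surface)
                oname = normalize_name(other.surface)
                if oname.startswith(gname + " "):
                    out.add(other.tax_id)
        return out

    relabel: dict[int, int] = {}
    for m in mentions:
        # already-resolved mentions are never treated as general again,
        # which makes the operation idempotent under the prefix heuristic
        if m.provenance == "specificity_inferred" or m.tax_id in relabel:
            continue
        desc = descendants_of(m)
        if desc:
            winner = min(desc, key=lambda t: (-counts[t], first_pos[t]))
            relabel[m.tax_id] = winner

    out: list[SpeciesMention] = []
    for m in mentions:
        if m.tax_id in relabel:
            out.append(replace(m, tax_id=relabel[m.tax_id],
                               provenance="specificity_inferred"))
        else:
            out.append(m)
    return out


def _is_ancestor(anc: int, node: int, hierarchy: Mapping[int, int]) -> bool:
    seen = set()
    cur = node
    while cur in hierarchy and cur not in seen:
        seen.add(cur)
        cur = hierarchy[cur]
        if cur == anc:
            return True
    return False


def recognize_all(
    doc: Document,
    lex: SpeciesLexicon,
    cells: Optional[CellLineLexicon] = None,
    hierarchy: Optional[Mapping[int, int]] = None,
) -> list[SpeciesMention]:
    """Full recognition: dictionary lookup + cell rule + specificity inference.

    Cell-derived mentions whose span overlaps a dictionary mention are
    dropped (the dictionary reading wins).  Output is sorted by start.
    """
    mentions = detect_species_mentions(doc, lex)
    if cells is not None and len(cells):
        taken = [(m.start, m.end) for m in mentions]
        for cm in detect_cell_line_species(doc, cells):
            if not any(cm.start < e and s < cm.end for s, e in taken):
                mentions.append(cm)
    mentions.sort(key=lambda m: (m.start, m.end))
    return infer_specific_species(mentions, hierarchy)
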