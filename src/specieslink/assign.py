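"""The gene-species assignment cascade.

For each pre-tagged gene mention the rules fire strictly in order and the
first one producing a taxonomy id wins:

1. **prefix** -- a lowercase organism-abbreviation letter directly before
   an uppercase letter at the head of the gene symbol (``hRrp46p`` ->
   human).
2. **cooccurrence** -- a species mention in the gene's sentence; mentions
   to the left of the gene beat mentions to its right, and on each side
   the mention closest to the gene wins.
3. **focus** -- the document's focus species: the species with the highest
   weighted mention count, title mentions counting double; ties broken by
   corpus-global frequency rank (never randomly).
4. **sri** -- for documents with no species mention at all, the cue-word
   Species Represented Indicator model over {human, mouse, yeast, fly}.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from specieslink.lexicon import GlobalFrequencyTable, PrefixMap, global_rank
from specieslink.preprocess import Document, GeneMention
from specieslink.recognize import SpeciesMention
from specieslink.sri import SRIModel, sri_infer, tokenize

RULES = ("prefix", "cooccurrence", "focus", "sri", "none")


@dataclass(frozen=True)
class Assignment:
    """One gene linked to a species, labeled with the cascade stage used."""

    gene: GeneMention
    tax_id: Optional[int]
    rule: str

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown rule label {self.rule!r}")
        if (self.rule == "none") != (self.tax_id is None):
            raise ValueError("rule is 'none' iff tax_id is absent")


@dataclass(frozen=True)
class FocusSpeciesResult:
    """Outcome of focus-species computation, with the weighted tally kept
    for inspection and evaluation."""

    tax_id: Optional[int]
    weighted_counts: dict[int, int] = field(default_factory=dict)
    tie_broken: bool = False


_PREFIX_PATTERN = re.compile(r"^([a-z])[A-Z]")


def assign_by_prefix(
    gene: GeneMention,
    pmap: PrefixMap,
    doc_species: Optional[set[int]] = None,
    strict: bool = False,
) -> Optional[int]:
    """Prefix rule: one lowercase organism letter heading the gene symbol.

    Fires only on a lowercase-letter-then-uppercase-letter head whose
    letter is in the prefix map.  By default the abbreviated organism need
    not be mentioned in the document; ``strict=True`` additionally requires
    its tax_id to appear in ``doc_species``.
    """
    m = _PREFIX_PATTERN.match(gene.surface)
    if not m:
        return None
    tax_id = pmap.get(m.group(1))
    if tax_id is None:
        return None
    if strict and (doc_species is None or tax_id not in doc_species):
        return None
    return tax_id


def assign_by_cooccurrence(
    gene: GeneMention, sentence_species: Sequence[SpeciesMention]
) -> Optional[int]:
    """Co-occurring-word rule: nearest species in the gene's sentence.

    Left-side mentions (ending at or before the gene start) take priority
    over right-side ones; within a side the smallest character gap wins,
    and an exact distance tie goes to the earlier mention.
    """
    left = [m for m in sentence_species if m.end <= gene.start]
    if left:
        return min(left, key=lambda m: (gene.start - m.end, m.start)).tax_id
    right = [m for m in sentence_species if m.start >= gene.end]
    if right:
        return min(right, key=lambda m: (m.start - gene.end, m.start)).tax_id
    return None


def compute_focus_species(
    doc: Document,
    mentions: Sequence[SpeciesMention],
    freq: GlobalFrequencyTable,
) -> FocusSpeciesResult:
    """Focus species: most-discussed organism, title mentions counted twice.

    Weighted count per species = 2 x (title mentions) + (other mentions).
    Ties between top-weighted species resolve by corpus-global frequency
    rank; an empty mention list yields an absent focus.
    """
    weighted: Counter[int] = Counter()
    for m in mentions:
        sent = doc.sentences[m.sid] if 0 <= m.sid < len(doc.sentences) else None
        in_title = sent is not None and sent.section_label == "title"
        weighted[m.tax_id] += 2 if in_title else 1
    if not weighted:
        return FocusSpeciesResult(tax_id=None)
    top = max(weighted.values())
    tied = {t for t, c in weighted.items() if c == top}
    if len(tied) == 1:
        return FocusSpeciesResult(tax_id=next(iter(tied)),
                                  weighted_counts=dict(weighted))
    return FocusSpeciesResult(tax_id=global_rank(freq, tied),
                              weighted_counts=dict(weighted), tie_broken=True)


def assign_all(
    doc: Document,
    genes: Sequence[GeneMention],
    mentions: Sequence[SpeciesMention],
    pmap: PrefixMap,
    freq: GlobalFrequencyTable,
    sri_model: Optional[SRIModel] = None,
    strict_prefix: bool = False,
) -> list[Assignment]:
    """Run the full cascade for every gene of one document.

    Stages are tried strictly in order prefix -> cooccurrence -> focus ->
    sri; the first stage producing a tax_id is recorded as the assignment's
    rule.  The SRI stage is reached only when the document carries no
    species mention (focus absent); without an SRI model such genes come
    back with rule ``none``.
    """
    doc_species = {m.tax_id for m in mentions}
    by_sid: dict[int, list[SpeciesMention]] = {}
    for m in mentions:
        by_sid.setdefault(m.sid, []).append(m)
    focus = compute_focus_species(doc, mentions, freq)

    sri_tax: Optional[int] = None
    if focus.tax_id is None and sri_model is not None:
        sri_tax = sri_infer(tokenize(doc.full_text), sri_model, freq)

    out: list[Assignment] = []
    for gene in genes:
        tax = assign_by_prefix(gene, pmap, doc_species, strict=strict_prefix)
        if tax is not None:
            out.append(Assignment(gene=gene, tax_id=tax, rule="prefix"))
            continue
        tax = assign_by_cooccurrence(gene, by_sid.get(gene.sid, []))
        if tax is not None:
            out.append(Assignment(gene=gene, tax_id=tax, rule="cooccurrence"))
            continue
        if focus.tax_id is not None:
            out.append(Assignment(gene=gene, tax_id=focus.tax_id, rule="focus"))
            continue
        if sri_tax is not None:
            out.append(Assignment(gene=gene, tax_id=sri_tax, rule="sri"))
            continue
        out.append(Assignment(gene=gene, tax_id=None, rule="none"))
    return out
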