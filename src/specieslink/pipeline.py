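"""End-to-end tagging: preprocess -> recognize -> assign for whole corpora."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from specieslink.assign import Assignment, assign_all
from specieslink.lexicon import (
    CellLineLexicon,
    GlobalFrequencyTable,
    PrefixMap,
    SpeciesLexicon,
    default_cell_lexicon,
    default_frequency_table,
    default_hierarchy,
    default_prefix_map,
    default_species_lexicon,
)
from specieslink.preprocess import Document, attach_gene_mentions
from specieslink.recognize import SpeciesMention, recognize_all
from specieslink.sri import SRIModel, default_sri_model


@dataclass
class Resources:
    """The lexical tables and models one tagging run depends on."""

    species: SpeciesLexicon
    cells: Optional[CellLineLexicon]
    prefix_map: PrefixMap
    frequency: GlobalFrequencyTable
    sri_model: Optional[SRIModel]
    hierarchy: Optional[dict[int, int]] = None
    strict_prefix: bool = False

    @classmethod
    def default(cls, **overrides) -> "Resources":
        base = dict(
            species=default_species_lexicon(),
            cells=default_cell_lexicon(),
            prefix_map=default_prefix_map(),
            frequency=default_frequency_table(),
            sri_model=default_sri_model(),
            hierarchy=default_hierarchy(),
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class TaggedDocument:
    document: Document
    mentions: list[SpeciesMention] = field(default_factory=list)
    assignments: list[Assignment] = field(default_factory=list)


def tag_document(
    doc: Document,
    res: Resources,
    gene_spans: Sequence[tuple[int, int]] = (),
) -> TaggedDocument:
    """Recognize species mentions and assign a species to each gene span."""
    mentions = recognize_all(doc, res.species, res.cells, res.hierarchy)
    genes = attach_gene_mentions(doc, gene_spans)
    assignments = assign_all(doc, genes, mentions, res.prefix_map,
                             res.frequency, res.sri_model,
                             strict_prefix=res.strict_prefix)
    return TaggedDocument(document=doc, mentions=mentions, assignments=assignments)


def tag_corpus(
    documents: Sequence[Document],
    res: Resources,
    gene_spans: Optional[Mapping[str, Sequence[tuple[int, int]]]] = None,
) -> dict[str, TaggedDocument]:
    """Tag every document; returns results keyed and ordered by doc_id."""
    out: dict[str, TaggedDocument] = {}
    for doc in sorted(documents, key=lambda d: d.doc_id):
        spans = gene_spans.get(doc.doc_id, ()) if gene_spans else ()
        out[doc.doc_id] = tag_document(doc, res, spans)
    return out
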