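"""Dictionary matching, the cell-name rule, specificity inference."""

import random

import pytest

from specieslink.lexicon import CellLineLexicon, SpeciesLexicon, default_cell_lexicon
from specieslink.preprocess import Document
from specieslink.recognize import (
    detect_cell_line_species,
    detect_species_mentions,
    infer_specific_species,
    recognize_all,
)

from conftest import make_doc, oracle_matches, random_document_text


def bare_doc(text: str) -> Document:
    return Document(doc_id="r", sections=[], full_text=text, sentences=[])


class TestDictionaryMatching:
    def test_strain_name_with_period_and_hyphen(self, mini_lexicon):
        doc = make_doc("A study.", "Growth in E. coli K-12 cultures was rapid.")
        mentions = detect_species_mentions(doc, mini_lexicon)
        assert [(m.surface, m.tax_id) for m in mentions] == [("E. coli K-12", 83333)]

    def test_vernacular_term(self, mini_lexicon):
        doc = make_doc("A study.", "We purified porcine insulin.")
        [m] = detect_species_mentions(doc, mini_lexicon)
        assert (m.surface, m.tax_id) == ("porcine", 9823)

    def test_empty_document_text(self, mini_lexicon):
        assert detect_species_mentions(bare_doc(""), mini_lexicon) == []

    def test_token_boundaries_suppress_embedded_matches(self, mini_lexicon):
        doc = bare_doc("rats ratx arat rat")
        mentions = detect_species_mentions(doc, mini_lexicon)
        assert [m.surface for m in mentions] == ["rat"]

    def test_case_insensitive_and_sorted(self, mini_lexicon):
        doc = bare_doc("MOUSE then Human")
        mentions = detect_species_mentions(doc, mini_lexicon)
        assert [m.tax_id for m in mentions] == [10090, 9606]
        assert mentions == sorted(mentions, key=lambda m: m.start)

    def test_leftmost_longest_on_nested_names(self, mini_lexicon):
        doc = bare_doc("E. coli K-12 and E. coli strains")
        mentions = detect_species_mentions(doc, mini_lexicon)
        assert [(m.surface, m.tax_id) for m in mentions] == [
            ("E. coli K-12", 83333),
            ("E. coli", 562),
        ]

    def test_matcher_agrees_with_bruteforce_oracle(self, mini_lexicon):
        rng = random.Random(20120605)
        for _ in range(300):
            text = random_document_text(rng, mini_lexicon)
            got = [
                (m.start, m.end, m.tax_id)
                for m in detect_species_mentions(bare_doc(text), mini_lexicon)
            ]
            assert got == oracle_matches(text, mini_lexicon), text

    def test_determinism(self, mini_lexicon):
        doc = make_doc("Human study.", "Mouse and rat were compared.")
        a = detect_species_mentions(doc, mini_lexicon)
        assert a == detect_species_mentions(doc, mini_lexicon)


class TestCellNameRule:
    def test_adjacent_cells_token(self):
        doc = make_doc("A study.", "HeLa cells were cultured.")
        [m] = detect_cell_line_species(doc, default_cell_lexicon())
        assert (m.surface, m.tax_id, m.provenance) == ("HeLa", 9606, "cell_line")

    def test_non_adjacent_within_noun_phrase(self):
        doc = make_doc("A study.", "The HeLa cancer cell line grew fast.")
        [m] = detect_cell_line_species(doc, default_cell_lexicon())
        assert m.tax_id == 9606
        assert doc.full_text[m.start:m.end] == "HeLa"

    def test_cells_in_next_sentence_does_not_fire(self):
        doc = make_doc("A study.", "HeLa was cultured. The cells grew.")
        assert detect_cell_line_species(doc, default_cell_lexicon()) == []

    def test_function_word_breaks_phrase(self):
        doc = make_doc("A study.", "HeLa was of interest to cell biologists.")
        assert detect_cell_line_species(doc, default_cell_lexicon()) == []

    def test_window_limit(self):
        doc = make_doc("A study.", "HeLa derived tumor xenograft model sample cells grew.")
        assert detect_cell_line_species(doc, default_cell_lexicon()) == []

    def test_mouse_cell_line(self):
        doc = make_doc("A study.", "3T3 cells were transfected.")
        [m] = detect_cell_line_species(doc, default_cell_lexicon())
        assert m.tax_id == 10090


class TestSpecificityInference:
    def test_general_relabelled_to_specific(self, mini_lexicon):
        doc = make_doc("On Arabidopsis.", "Arabidopsis thaliana was grown.")
        mentions = infer_specific_species(detect_species_mentions(doc, mini_lexicon))
        assert {m.tax_id for m in mentions} == {3702}
        general = next(m for m in mentions if m.surface == "Arabidopsis")
        assert general.provenance == "specificity_inferred"

    def test_no_specific_co_mention_unchanged(self, mini_lexicon):
        doc = make_doc("On Arabidopsis.", "It was grown in soil.")
        mentions = infer_specific_species(detect_species_mentions(doc, mini_lexicon))
        assert [m.tax_id for m in mentions] == [3701]
        assert all(m.provenance == "dictionary" for m in mentions)

    def test_tie_resolved_by_mention_count_then_first_occurrence(self):
        lex = SpeciesLexicon(
            entries={"arabidopsis": 3701, "arabidopsis thaliana": 3702,
                     "arabidopsis lyrata": 59689},
            sources={},
        )
        doc = make_doc(
            "Arabidopsis genomes.",
            "Arabidopsis lyrata was sequenced. Arabidopsis thaliana was "
            "sequenced. Arabidopsis thaliana is a model.",
        )
        mentions = infer_specific_species(detect_species_mentions(doc, lex))
        general = next(m for m in mentions if m.surface == "Arabidopsis")
        assert general.tax_id == 3702  # thaliana mentioned twice, lyrata once

    def test_hierarchy_route(self, mini_lexicon):
        hierarchy = {83333: 562}
        doc = make_doc("On E. coli.", "The E. coli K-12 strain was used.")
        mentions = infer_specific_species(
            detect_species_mentions(doc, mini_lexicon), hierarchy
        )
        assert {m.tax_id for m in mentions} == {83333}

    def test_spans_never_change_and_idempotent(self, mini_lexicon):
        doc = make_doc("On Arabidopsis.", "Arabidopsis thaliana was grown.")
        before = detect_species_mentions(doc, mini_lexicon)
        once = infer_specific_species(before)
        twice = infer_specific_species(once)
        assert [(m.start, m.end) for m in once] == [(m.start, m.end) for m in before]
        assert once == twice


def test_recognize_all_prefers_dictionary_over_cell(mini_lexicon):
    cells = CellLineLexicon(entries={"human": 9606}, extension=set())
    doc = make_doc("A study.", "The human cells were examined.")
    mentions = recognize_all(doc, mini_lexicon, cells)
    assert [m.provenance for m in mentions] == ["dictionary"]
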