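"""The prefix / cooccurrence / focus / SRI cascade."""

import pytest

from specieslink.assign import (
    Assignment,
    assign_all,
    assign_by_cooccurrence,
    assign_by_prefix,
    compute_focus_species,
)
from specieslink.lexicon import GlobalFrequencyTable, default_prefix_map
from specieslink.preprocess import GeneMention, attach_gene_mentions
from specieslink.recognize import SpeciesMention, recognize_all
from specieslink.sri import default_sri_model

from conftest import make_doc


def gene(surface: str, start: int = 50, sid: int = 1) -> GeneMention:
    return GeneMention(start=start, end=start + len(surface), surface=surface, sid=sid)


def mention(start: int, end: int, tax_id: int, sid: int = 1) -> SpeciesMention:
    return SpeciesMention(start=start, end=end, surface="x" * (end - start),
                          tax_id=tax_id, provenance="dictionary", sid=sid)


class TestPrefixRule:
    @pytest.mark.parametrize(
        "surface, expected",
        [
            ("hRrp46p", 9606),
            ("mSos1", 10090),
            ("rGene1", 10116),
            ("Rrp46", None),       # no lowercase-then-uppercase head
            ("hsp70", None),       # second char not uppercase
            ("qRrp4", None),       # letter not in the map
        ],
    )
    def test_pattern_and_lookup(self, surface, expected):
        assert assign_by_prefix(gene(surface), default_prefix_map(), set()) == expected

    def test_default_ignores_document_species(self):
        # the abbreviated organism need not be mentioned in the document
        assert assign_by_prefix(gene("hRrp46p"), default_prefix_map(), {10090}) == 9606

    def test_strict_mode_requires_document_membership(self):
        pmap = default_prefix_map()
        assert assign_by_prefix(gene("hRrp46p"), pmap, {10090}, strict=True) is None
        assert assign_by_prefix(gene("hRrp46p"), pmap, {9606}, strict=True) == 9606


class TestCooccurrenceRule:
    def test_single_left_mention(self):
        assert assign_by_cooccurrence(gene("TP53", start=50),
                                      [mention(10, 15, 9606)]) == 9606

    def test_left_priority_over_right(self):
        ms = [mention(10, 15, 10090), mention(70, 75, 9606)]
        assert assign_by_cooccurrence(gene("G1", start=50), ms) == 10090

    def test_closest_on_left_wins(self):
        ms = [mention(5, 10, 10090), mention(30, 35, 9606)]
        assert assign_by_cooccurrence(gene("G1", start=50), ms) == 9606

    def test_closest_on_right_when_no_left(self):
        ms = [mention(70, 75, 9606), mention(90, 95, 10090)]
        assert assign_by_cooccurrence(gene("G1", start=50), ms) == 9606

    def test_equidistant_tie_goes_to_earlier_mention(self):
        ms = [mention(40, 45, 10090), mention(40, 45, 9606)]
        # identical spans: earlier in list order shares start; min picks first
        assert assign_by_cooccurrence(gene("G1", start=50), ms) == 10090

    def test_empty_sentence(self):
        assert assign_by_cooccurrence(gene("G1"), []) is None

    def test_left_priority_property(self):
        # inserting a left mention never yields a right-side winner
        right_only = [mention(70, 75, 9606)]
        for left_end in range(5, 48, 7):
            ms = right_only + [mention(left_end - 4, left_end, 7227)]
            assert assign_by_cooccurrence(gene("G1", start=50), ms) == 7227


class TestFocusSpecies:
    freq = GlobalFrequencyTable({9606: 100, 10116: 90, 10090: 80})

    def test_title_double_weight_tie_broken_to_human(self):
        doc = make_doc("A human study.", "The mouse data came first. More mouse data.")
        mentions = [
            SpeciesMention(start=doc.full_text.index("human"),
                           end=doc.full_text.index("human") + 5,
                           surface="human", tax_id=9606, provenance="dictionary",
                           sid=0),
            mention(20, 25, 10090, sid=1),
            mention(45, 50, 10090, sid=2),
        ]
        result = compute_focus_species(doc, mentions, self.freq)
        assert result.weighted_counts == {9606: 2, 10090: 2}
        assert result.tie_broken
        assert result.tax_id == 9606

    def test_single_species(self):
        doc = make_doc("A title.", "Something here.")
        result = compute_focus_species(doc, [mention(9, 14, 7227, sid=1)], self.freq)
        assert result.tax_id == 7227
        assert not result.tie_broken

    def test_no_mentions(self):
        doc = make_doc("A title.")
        assert compute_focus_species(doc, [], self.freq).tax_id is None

    def test_title_weight_monotonicity(self):
        # moving one mention of a species into the title never lowers its count
        doc = make_doc("A human title.", "Flies and more flies.")
        base = [mention(20, 25, 7227, sid=1), mention(30, 35, 9606, sid=1)]
        h = doc.full_text.index("human")
        moved = [mention(20, 25, 7227, sid=1),
                 SpeciesMention(start=h, end=h + 5, surface="human", tax_id=9606,
                                provenance="dictionary", sid=0)]
        before = compute_focus_species(doc, base, self.freq).weighted_counts[9606]
        after = compute_focus_species(doc, moved, self.freq).weighted_counts[9606]
        assert after >= before


class TestCascade:
    def _tag(self, resources, title, abstract, gene_surface):
        doc = make_doc(title, abstract)
        start = doc.full_text.index(gene_surface)
        genes = attach_gene_mentions(doc, [(start, start + len(gene_surface))])
        mentions = recognize_all(doc, resources.species, resources.cells)
        return assign_all(doc, genes, mentions, resources.prefix_map,
                          resources.frequency, resources.sri_model)

    def test_prefix_beats_focus(self, resources):
        [a] = self._tag(resources, "A mouse study.",
                        "In mouse tissue we cloned hRrp46p. Mouse data followed.",
                        "hRrp46p")
        assert (a.rule, a.tax_id) == ("prefix", 9606)

    def test_focus_used_for_species_free_sentence(self, resources):
        [a] = self._tag(resources, "A mouse study.",
                        "Mouse models abound. The Abc1 gene is unmapped.", "Abc1")
        assert (a.rule, a.tax_id) == ("focus", 10090)

    def test_sri_used_in_species_free_document(self, resources):
        [a] = self._tag(resources, "A study.",
                        "The cohort was followed for a decade. Gx1 was measured.",
                        "Gx1")
        assert (a.rule, a.tax_id) == ("sri", 9606)

    def test_rule_none_without_sri_model(self, resources):
        doc = make_doc("A study.", "Nothing biological here. Gx1 was measured.")
        start = doc.full_text.index("Gx1")
        genes = attach_gene_mentions(doc, [(start, start + 3)])
        [a] = assign_all(doc, genes, [], resources.prefix_map,
                         resources.frequency, sri_model=None)
        assert (a.rule, a.tax_id) == ("none", None)

    def test_every_gene_gets_exactly_one_record(self, resources):
        doc = make_doc("A mouse study.", "Mouse genes Aaa1 and Bbb2 and cCcc3.")
        spans = [(doc.full_text.index(s), doc.full_text.index(s) + len(s))
                 for s in ("Aaa1", "Bbb2", "cCcc3")]
        genes = attach_gene_mentions(doc, spans)
        mentions = recognize_all(doc, resources.species, resources.cells)
        assignments = assign_all(doc, genes, mentions, resources.prefix_map,
                                 resources.frequency, resources.sri_model)
        assert len(assignments) == len(genes)
        assert all(a.rule != "none" for a in assignments)


def test_assignment_invariant_rule_none_iff_absent():
    g = GeneMention(start=0, end=2, surface="Gx", sid=0)
    with pytest.raises(ValueError):
        Assignment(gene=g, tax_id=None, rule="focus")
    with pytest.raises(ValueError):
        Assignment(gene=g, tax_id=9606, rule="none")
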