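"""Mention P/R/F and assignment accuracy with per-rule breakdown."""

import random

import pytest

from specieslink.assign import Assignment
from specieslink.evaluate import assignment_accuracy, mention_prf
from specieslink.io_formats import GoldRecord
from specieslink.preprocess import GeneMention


def key(doc, s, e, t):
    return (doc, s, e, t)


class TestMentionPRF:
    def test_perfect(self):
        gold = [key("d", 0, 5, 9606), key("d", 10, 15, 10090)]
        assert mention_prf(gold, gold) == (1.0, 1.0, 1.0)

    def test_two_correct_one_spurious_one_missed(self):
        gold = [key("d", 0, 5, 9606), key("d", 10, 15, 10090), key("d", 20, 25, 7227)]
        pred = [key("d", 0, 5, 9606), key("d", 10, 15, 10090), key("d", 30, 35, 4932)]
        p, r, f = mention_prf(pred, gold)
        assert (p, r, f) == (pytest.approx(2 / 3),) * 3

    def test_no_predictions(self):
        assert mention_prf([], [key("d", 0, 5, 9606)]) == (0.0, 0.0, 0.0)

    def test_no_gold(self):
        assert mention_prf([key("d", 0, 5, 9606)], []) == (0.0, 0.0, 0.0)

    def test_taxid_must_match(self):
        gold = [key("d", 0, 5, 9606)]
        pred = [key("d", 0, 5, 10090)]
        assert mention_prf(pred, gold)[0] == 0.0

    def test_overlap_mode_is_lenient(self):
        gold = [key("d", 0, 5, 9606)]
        pred = [key("d", 2, 7, 9606)]
        assert mention_prf(pred, gold)[0] == 0.0
        assert mention_prf(pred, gold, overlap=True)[0] == 1.0


def assignment(doc_start_end, tax_id, rule):
    _, s, e = doc_start_end
    gene = GeneMention(start=s, end=e, surface="G" * (e - s), sid=0)
    return Assignment(gene=gene, tax_id=tax_id, rule=rule)


class TestAssignmentAccuracy:
    def setup_method(self):
        self.gold = [
            GoldRecord("d1", 0, 4, "GGGG", 9606),
            GoldRecord("d1", 10, 14, "GGGG", 10090),
            GoldRecord("d2", 0, 4, "GGGG", 4932),
            GoldRecord("d2", 10, 14, "GGGG", 7227),
            GoldRecord("d2", 20, 24, "GGGG", 9606),
        ]

    def predictions(self, wrong_idx=()):
        golds = list(self.gold)
        rules = ["prefix", "cooccurrence", "focus", "sri", "focus"]
        by_doc: dict[str, list[Assignment]] = {}
        for i, (g, rule) in enumerate(zip(golds, rules)):
            tax = g.tax_id if i not in wrong_idx else g.tax_id + 1
            by_doc.setdefault(g.doc_id, []).append(
                assignment((g.doc_id, g.start, g.end), tax, rule))
        return by_doc

    def test_all_correct(self):
        report = assignment_accuracy(self.predictions(), self.gold)
        assert report.accuracy == 1.0
        assert all(row.errors == 0 for row in report.per_rule.values())

    def test_four_of_five(self):
        report = assignment_accuracy(self.predictions(wrong_idx={1}), self.gold)
        assert report.accuracy == pytest.approx(0.8)
        assert report.per_rule["cooccurrence"].errors == 1

    def test_counts_conserved(self):
        report = assignment_accuracy(self.predictions(wrong_idx={0, 3}), self.gold)
        assert report.total_genes == len(self.gold)
        assert report.total_errors == 2
        assert report.accuracy == pytest.approx(1 - 2 / 5)

    def test_unmatched_gold_counts_as_none_error(self):
        preds = self.predictions()
        preds["d2"] = preds["d2"][:-1]  # drop one assignment
        report = assignment_accuracy(preds, self.gold)
        assert report.per_rule["none"].applicable == 1
        assert report.per_rule["none"].errors == 1
        assert report.total_genes == len(self.gold)

    def test_permutation_invariance(self):
        rng = random.Random(5)
        gold = list(self.gold)
        base = assignment_accuracy(self.predictions(wrong_idx={2}), gold)
        for _ in range(5):
            rng.shuffle(gold)
            report = assignment_accuracy(self.predictions(wrong_idx={2}), gold)
            assert report.accuracy == base.accuracy
            assert {r: (row.applicable, row.errors)
                    for r, row in report.per_rule.items()} == \
                   {r: (row.applicable, row.errors)
                    for r, row in base.per_rule.items()}

    def test_accuracy_identity_with_rule_errors(self):
        report = assignment_accuracy(self.predictions(wrong_idx={0, 2, 4}), self.gold)
        assert report.accuracy == pytest.approx(
            1 - report.total_errors / report.total_genes)

    def test_ancestor_match_configurable(self):
        gold = [GoldRecord("d", 0, 4, "GGGG", 562)]
        preds = {"d": [assignment(("d", 0, 4), 83333, "focus")]}
        strict = assignment_accuracy(preds, gold)
        assert strict.accuracy == 0.0
        lenient = assignment_accuracy(preds, gold, ancestor_ok=True,
                                      hierarchy={83333: 562})
        assert lenient.accuracy == 1.0

    def test_report_serializers(self):
        report = assignment_accuracy(self.predictions(wrong_idx={1}), self.gold)
        assert "accuracy" in report.to_json()
        table = report.to_table()
        assert "total" in table and "100.0%" in table
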