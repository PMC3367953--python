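"""Scoring: mention-level P/R/F and assignment accuracy with rule breakdown.

Mention detection is scored with exact-span, exact-taxid matching (the
strictest criterion; an overlap mode exists but is explicitly
non-canonical).  Assignment is scored as plain accuracy over gold records,
broken down by the cascade rule that produced each prediction, so a report
mirrors the "applicable genes / errors / accuracy per rule" table shape
commonly used for cascade error analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from specieslink.assign import RULES, Assignment
from specieslink.io_formats import GoldRecord
from specieslink.recognize import SpeciesMention

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RuleRow:
    applicable: int
    errors: int

    @property
    def accuracy(self) -> float:
        return 1.0 - self.errors / self.applicable if self.applicable else 1.0


@dataclass
class EvalReport:
    precision: Optional[float] = None
    recall: Optional[float] = None
    f_measure: Optional[float] = None
    accuracy: Optional[float] = None
    per_rule: dict[str, RuleRow] = field(default_factory=dict)

    @property
    def total_genes(self) -> int:
        return sum(r.applicable for r in self.per_rule.values())

    @property
    def total_errors(self) -> int:
        return sum(r.errors for r in self.per_rule.values())

    def to_json(self) -> str:
        payload: dict = {}
        for key in ("precision", "recall", "f_measure", "accuracy"):
            val = getattr(self, key)
            if val is not None:
                payload[key] = val
        if self.per_rule:
            payload["per_rule"] = {
                rule: {"applicable": row.applicable, "errors": row.errors,
                       "accuracy": row.accuracy}
                for rule, row in self.per_rule.items()
            }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_table(self) -> str:
        lines = []
        if self.precision is not None:
            lines.append(f"precision {self.precision:.4f}  recall "
                         f"{self.recall:.4f}  F {self.f_measure:.4f}")
        if self.per_rule:
            total = self.total_genes or 1
            lines.append(f"{'rule':<14}{'applicable':>12}{'errors':>8}{'accuracy':>10}")
            for rule, row in self.per_rule.items():
                pct = 100.0 * row.applicable / total
                lines.append(f"{rule:<14}{row.applicable:>7}({pct:5.2f}%)"
                             f"{row.errors:>8}{100 * row.accuracy:>9.2f}%")
            lines.append(f"{'total':<14}{self.total_genes:>7}(100.0%)"
                         f"{self.total_errors:>8}"
                         f"{100 * (self.accuracy or 0):>9.2f}%")
        return "\n".join(lines)


MentionKey = tuple[str, int, int, int]  # doc_id, start, end, tax_id


def _mention_key(doc_id: str, m: SpeciesMention) -> MentionKey:
    return (doc_id, m.start, m.end, m.tax_id)


def mention_prf(
    predicted: Sequence[MentionKey], gold: Sequence[MentionKey],
    overlap: bool = False,
) -> tuple[float, float, float]:
    """Precision/recall/F over (doc_id, start, end, tax_id) mention keys.

    A prediction is a true positive iff span and tax_id match exactly
    (canonical mode).  ``overlap=True`` relaxes span matching to any
    overlap with a same-taxid gold span; this mode is non-canonical and
    intended only for diagnostics.  Empty-denominator conventions:
    precision = 0 with no predictions, recall = 0 with no gold, F = 0 when
    either is 0.
    """
    pred_set, gold_set = set(predicted), set(gold)
    if overlap:
        tp_pred = sum(
            1 for d, s, e, t in pred_set
            if any(d == gd and t == gt and s < ge and gs < e
                   for gd, gs, ge, gt in gold_set)
        )
        tp_gold = sum(
            1 for gd, gs, ge, gt in gold_set
            if any(gd == d and gt == t and s < ge and gs < e
                   for d, s, e, t in pred_set)
        )
    else:
        tp_pred = tp_gold = len(pred_set & gold_set)
    precision = tp_pred / len(pred_set) if pred_set else 0.0
    recall = tp_gold / len(gold_set) if gold_set else 0.0
    f = (2 * precision * recall / (precision + recall)
         if precision > 0 and recall > 0 else 0.0)
    return precision, recall, f


def mention_prf_report(
    predicted_by_doc: Mapping[str, Sequence[SpeciesMention]],
    gold: Sequence[MentionKey],
    overlap: bool = False,
) -> EvalReport:
    pred = [
        _mention_key(doc_id, m)
        for doc_id, ms in sorted(predicted_by_doc.items())
        for m in ms
    ]
    p, r, f = mention_prf(pred, gold, overlap=overlap)
    return EvalReport(precision=p, recall=r, f_measure=f)


def assignment_accuracy(
    assignments_by_doc: Mapping[str, Sequence[Assignment]],
    gold: Sequence[GoldRecord],
    ancestor_ok: bool = False,
    hierarchy: Optional[Mapping[int, int]] = None,
) -> EvalReport:
    """Score gene-species assignments against gold records.

    Gold records match predictions by (doc_id, start, end).  An unmatched
    gold record counts as an error under rule ``none``.  By default a
    predicted sub-taxon of the gold species (e.g. a strain versus its
    species) is incorrect; ``ancestor_ok=True`` with a hierarchy accepts
    it.  The per-rule rows partition the gold set, so applicable counts sum
    to the gold size and per-rule errors sum to total errors.
    """
    index: dict[tuple[str, int, int], Assignment] = {}
    for doc_id, assigns in assignments_by_doc.items():
        for a in assigns:
            index[(doc_id, a.gene.start, a.gene.end)] = a

    applicable = {rule: 0 for rule in RULES}
    errors = {rule: 0 for rule in RULES}
    for record in gold:
        a = index.get((record.doc_id, record.start, record.end))
        if a is None:
            logger.warning("no assignment for gold record %s:(%d,%d)",
                           record.doc_id, record.start, record.end)
            applicable["none"] += 1
            errors["none"] += 1
            continue
        applicable[a.rule] += 1
        if not _correct(a.tax_id, record.tax_id, ancestor_ok, hierarchy):
            errors[a.rule] += 1

    total = len(gold)
    total_errors = sum(errors.values())
    per_rule = {
        rule: RuleRow(applicable=applicable[rule], errors=errors[rule])
        for rule in RULES
        if applicable[rule] or rule != "none"
    }
    accuracy = (total - total_errors) / total if total else 1.0
    return EvalReport(accuracy=accuracy, per_rule=per_rule)


def _correct(
    predicted: Optional[int], gold: int,
    ancestor_ok: bool, hierarchy: Optional[Mapping[int, int]],
) -> bool:
    if predicted is None:
        return False
    if predicted == gold:
        return True
    if ancestor_ok and hierarchy is not None:
        cur, seen = predicted, set()
        while cur in hierarchy and cur not in seen:
            seen.add(cur)
            cur = hierarchy[cur]
            if cur == gold:
                return True
    return False
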