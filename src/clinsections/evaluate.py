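"""Chunk-level exact-span evaluation.

A predicted heading is correct only if its character interval equals a gold
heading's interval exactly; any other prediction is a false positive and any
missed gold heading a false negative, so a boundary error costs one of each.
Precision = TP / (TP + FP), recall = TP / (TP + FN), F is their harmonic
mean; zero denominators yield 0 by convention.  Corpus-level scores are
micro-averaged (counts pooled over documents).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .textmodel import HeadingSpan


@dataclass(frozen=True)
class EvalReport:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall, "f": self.f,
        }


def chunk_prf(gold: list[HeadingSpan], pred: list[HeadingSpan]) -> EvalReport:
    """Score one document's predictions against its gold spans.

    Matching is on (start, end) intervals only; duplicate predicted intervals
    are collapsed first (a tagger emits a span set, not a multiset).
    """
    gold_set = {s.interval() for s in gold}
    pred_set = {s.interval() for s in pred}
    tp = len(gold_set & pred_set)
    return EvalReport(tp=tp, fp=len(pred_set) - tp, fn=len(gold_set) - tp)


def aggregate(reports: list[EvalReport]) -> EvalReport:
    """Micro-average: pool TP/FP/FN then recompute P/R/F."""
    return EvalReport(
        tp=sum(r.tp for r in reports),
        fp=sum(r.fp for r in reports),
        fn=sum(r.fn for r in reports),
    )


@dataclass(frozen=True)
class RunDelta:
    """Signed P/R/F differences between two runs (a minus b)."""

    dp: float
    dr: float
    df: float


def compare_runs(a: EvalReport, b: EvalReport) -> RunDelta:
    return RunDelta(a.precision - b.precision, a.recall - b.recall, a.f - b.f)


def evaluate_documents(
    per_doc: dict[str, tuple[list[HeadingSpan], list[HeadingSpan]]],
) -> tuple[dict[str, EvalReport], EvalReport]:
    """Per-document and pooled reports for {doc_id: (gold, predicted)}."""
    reports = {doc_id: chunk_prf(g, p) for doc_id, (g, p) in sorted(per_doc.items())}
    return reports, aggregate(list(reports.values()))


def format_report(per_doc: dict[str, EvalReport], total: EvalReport) -> str:
    """Aligned plain-text table, one row per document plus the micro-average."""
    rows = [("document", "TP", "FP", "FN", "P", "R", "F")]
    for doc_id, r in per_doc.items():
        rows.append((doc_id, str(r.tp), str(r.fp), str(r.fn),
                     f"{r.precision:.4f}", f"{r.recall:.4f}", f"{r.f:.4f}"))
    rows.append(("ALL", str(total.tp), str(total.fp), str(total.fn),
                 f"{total.precision:.4f}", f"{total.recall:.4f}", f"{total.f:.4f}"))
    widths = [max(len(row[i]) for row in rows) for i in range(7)]
    lines = []
    for row in rows:
        lines.append("  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip())
    return "\n".join(lines) + "\n"


def report_json(per_doc: dict[str, EvalReport], total: EvalReport) -> str:
    return json.dumps(
        {"documents": {d: r.as_dict() for d, r in per_doc.items()}, "aggregate": total.as_dict()},
        indent=2,
    )
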