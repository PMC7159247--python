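"""Count-based binary-classification metrics and precision-recall curves.

Metrics count sequences, not bases: a 500 kb plasmid and a 500 bp plasmid
each contribute one unit.  Because metagenome assemblies are dominated by
short contigs, counting sequences is the stricter and more informative
convention — a classifier that only recovers a few long plasmids scores
near zero even though it recovers most plasmid *bases*.  A
length-weighted variant is provided to make that divergence measurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from plasq.training import CHROMOSOME, PLASMID

logger = logging.getLogger(__name__)


@dataclass
class MetricReport:
    """Confusion counts and the derived precision/recall/F1.

    Zero-denominator metrics are defined as 0 (not NaN) so reports
    aggregate cleanly; ``min_length`` records the strict length cutoff
    applied before counting (0 = none).
    """

    tp: float
    fp: float
    fn: float
    tn: float
    min_length: int = 0

    @property
    def n(self) -> float:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom > 0 else 0.0

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom > 0 else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


def score(
    results: Sequence,
    truth: Mapping[str, str],
    min_length: int = 0,
    length_weighted: bool = False,
) -> MetricReport:
    """Score classification results against per-sequence truth labels.

    Plasmid is the positive class.  Sequences with length <= ``min_length``
    are excluded before counting (cutoffs are strict, matching "> 500 bp"
    style stratification; ``min_length=0`` keeps everything).  With
    ``length_weighted=True`` each sequence contributes its length in bp
    instead of one count.

    Raises ``ValueError`` when a result id is missing from ``truth``.
    """
    tp = fp = fn = tn = 0.0
    for r in results:
        if r.id not in truth:
            raise ValueError(f"id {r.id!r} missing from truth labels")
        if min_length > 0 and r.length <= min_length:
            continue
        w = float(r.length) if length_weighted else 1.0
        pred_pos = r.label == PLASMID
        true_pos = truth[r.id] == PLASMID
        if pred_pos and true_pos:
            tp += w
        elif pred_pos and not true_pos:
            fp += w
        elif true_pos:
            fn += w
        else:
            tn += w
    report = MetricReport(tp=tp, fp=fp, fn=fn, tn=tn, min_length=min_length)
    if report.tp + report.fp == 0 or report.tp + report.fn == 0:
        logger.debug("degenerate metric denominator at min_length=%d", min_length)
    return report


def pr_curve(
    scored: Sequence[tuple[float, str]],
) -> tuple[list[tuple[float, float]], float, float]:
    """Precision-recall curve and its area.

    ``scored`` is a sequence of (probability, truth label) pairs with
    plasmid as the positive class.  The decision threshold is swept over
    the distinct scores in descending order; at each threshold t the point
    (recall, precision) of the rule "predict plasmid iff score >= t" is
    emitted.  The area is the step-wise (average-precision) sum
    ``sum((R_i - R_{i-1}) * P_i)``, which avoids the optimistic linear
    interpolation of the trapezoidal rule.

    Returns (points, area, baseline) where baseline is the positive
    fraction.  Raises ``ValueError`` unless both classes are present.
    """
    probs = np.array([p for p, _ in scored], dtype=np.float64)
    pos = np.array([lab == PLASMID for _, lab in scored], dtype=bool)
    n_pos = int(pos.sum())
    n_neg = len(pos) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("pr_curve needs at least one example of each class")
    order = np.argsort(-probs, kind="stable")
    probs, pos = probs[order], pos[order]
    points: list[tuple[float, float]] = []
    area = 0.0
    prev_recall = 0.0
    tp = fp = 0
    i = 0
    n = len(probs)
    while i < n:
        j = i
        while j < n and probs[j] == probs[i]:
            tp += int(pos[j])
            fp += int(not pos[j])
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        points.append((recall, precision))
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    baseline = n_pos / len(pos)
    return points, area, baseline


def length_stratified_report(
    results: Sequence,
    truth: Mapping[str, str],
    cutoffs: Sequence[int],
) -> list[MetricReport]:
    """One MetricReport per minimum-length cutoff (ascending)."""
    if list(cutoffs) != sorted(cutoffs):
        raise ValueError("cutoffs must be sorted ascending")
    return [score(results, truth, min_length=c) for c in cutoffs]


def write_report_tsv(reports: Sequence[MetricReport], path: str) -> None:
    """Stratified report TSV; rates as percentages with 2 decimals."""
    with open(path, "w") as fh:
        fh.write("min_length\tn\ttp\tfp\tfn\ttn\tprecision\trecall\tf1\n")
        for r in reports:
            fh.write(
                f"{r.min_length}\t{int(r.n)}\t{int(r.tp)}\t{int(r.fp)}\t"
                f"{int(r.fn)}\t{int(r.tn)}\t"
                f"{100 * r.precision:.2f}\t{100 * r.recall:.2f}\t{100 * r.f1:.2f}\n"
            )


def write_pr_curve_tsv(
    points: Sequence[tuple[float, float]], path: str
) -> None:
    with open(path, "w") as fh:
        fh.write("recall\tprecision\n")
        for recall, precision in points:
            fh.write(f"{recall:.6f}\t{precision:.6f}\n")
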