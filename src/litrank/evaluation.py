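"""Evaluation of ranked results against curated truth labels.

The positive class is set A ("interesting").  Given per-abstract relevance
scores and truth labels, this module computes confusion counts at a score
threshold, precision / recall / false-positive rate, the Matthews
correlation coefficient, and threshold sweeps for precision-recall and ROC
curves (with MCC reported multiplied by 100, as is conventional when
plotting it alongside percent-scale rates).

Truth labels may come from majority-vote curation: with an odd number of
independent annotators per abstract, the majority label is the "correct"
class and any disagreement flags the abstract as ambiguous.

Undefined ratios (zero denominators) are reported as ``None`` rather than
0 so that curve extremes are not silently distorted; MCC follows the
standard convention that a zero factor in its denominator yields 0.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence


@dataclass(frozen=True)
class ConfusionCounts:
    """Two-class confusion counts; positive class = set A."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @property
    def accuracy(self) -> float | None:
        return (self.TP + self.TN) / self.total if self.total else None


@dataclass(frozen=True)
class CurvePoint:
    threshold: float
    precision: float | None
    recall: float | None
    fpr: float | None
    mcc_times_100: float


def confusion(results: Sequence, truth: Mapping[int, str],
              threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts at a score threshold (assignment to A is strict >).

    ``results`` is any sequence of objects with ``pmid`` and ``score``
    attributes (e.g. :class:`litrank.pipeline.RankedResult`).  Every result
    PMID must carry a truth label.
    """
    missing = [r.pmid for r in results if r.pmid not in truth]
    if missing:
        raise KeyError(f"no truth label for PMIDs: {missing[:10]}"
                       + ("..." if len(missing) > 10 else ""))
    tp = fp = tn = fn = 0
    for r in results:
        predicted_a = r.score > threshold
        truth_a = truth[r.pmid] == "A"
        if predicted_a and truth_a:
            tp += 1
        elif predicted_a:
            fp += 1
        elif truth_a:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def precision_recall_fpr(c: ConfusionCounts,
                         ) -> tuple[float | None, float | None, float | None]:
    """(precision, recall, FPR); a ratio with zero denominator is None."""
    precision = c.TP / (c.TP + c.FP) if (c.TP + c.FP) else None
    recall = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else None
    fpr = c.FP / (c.FP + c.TN) if (c.FP + c.TN) else None
    return precision, recall, fpr


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1].

    +1 is a perfect prediction, 0 an average random one, -1 a perfectly
    inverted one.  Any zero factor in the denominator yields 0.
    """
    denom2 = ((c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN))
    if denom2 == 0:
        return 0.0
    return (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom2)


def sweep(results: Sequence, truth: Mapping[int, str],
          thresholds: Sequence[float] | None = None) -> list[CurvePoint]:
    """Metric curve over ascending thresholds.

    Default thresholds are the sorted distinct scores plus {0, 1}.  Recall
    and FPR are non-increasing as the threshold rises.
    """
    if thresholds is None:
        thresholds = sorted({r.score for r in results} | {0.0, 1.0})
    elif list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    curve = []
    for t in thresholds:
        c = confusion(results, truth, t)
        p, r, f = precision_recall_fpr(c)
        curve.append(CurvePoint(t, p, r, f, 100.0 * mcc(c)))
    return curve


def majority_vote(annotations: Mapping[int, Sequence[str]],
                  ) -> dict[int, tuple[str, bool]]:
    """Majority-vote truth from k independent annotators (k odd, default 3).

    Returns pmid -> (majority label, ambiguous); an abstract is ambiguous
    when any annotator disagreed with the majority.
    """
    out: dict[int, tuple[str, bool]] = {}
    for pmid, labels in annotations.items():
        if len(labels) % 2 == 0:
            raise ValueError(
                f"PMID {pmid}: need an odd number of annotators, got {len(labels)}")
        votes = Counter(labels)
        label, n = votes.most_common(1)[0]
        out[pmid] = (label, n < len(labels))
    return out


def write_curve_tsv(curve: Sequence[CurvePoint], path) -> None:
    """Export a metric curve as TSV; undefined ratios print as 'undefined'."""
    def fmt(v):
        return "undefined" if v is None else f"{v:.6g}"

    with open(path, "w") as fh:
        fh.write("threshold\tprecision\trecall\tfpr\tmcc_x100\n")
        for pt in curve:
            fh.write(f"{pt.threshold:.6g}\t{fmt(pt.precision)}\t{fmt(pt.recall)}\t"
                     f"{fmt(pt.fpr)}\t{pt.mcc_times_100:.6g}\n")


def read_truth_tsv(path) -> tuple[dict[int, str], dict[int, bool]]:
    """Read a truth TSV: ``pmid<TAB>label`` or ``pmid<TAB>l1<TAB>l2<TAB>l3``.

    Multi-column files are resolved by majority vote.  Returns the label
    map and the ambiguity map (empty flags for single-column files).
    """
    from pathlib import Path

    annotations: dict[int, list[str]] = {}
    single: dict[int, str] = {}
    multi = False
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        pmid = int(parts[0])
        labels = [p.strip() for p in parts[1:] if p.strip()]
        if len(labels) > 1:
            multi = True
        annotations[pmid] = labels
        single[pmid] = labels[0]
    if multi:
        voted = majority_vote(annotations)
        return ({p: lab for p, (lab, _) in voted.items()},
                {p: amb for p, (_, amb) in voted.items()})
    return single, {p: False for p in single}
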