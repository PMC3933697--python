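"""Classifier evaluation: per-term confusion metrics and per-IDR PR curves.

Two complementary views of performance:

* per term, at the 0.5 posterior operating point — sensitivity, specificity,
  precision and Matthews correlation coefficient (MCC) from cross-validated
  confusion counts, averaged over terms per feature family;
* per IDR, sweeping the posterior threshold p — each held-out IDR predicts a
  term set for its parent protein, compared against the protein's known
  (ancestor-expanded) term set to give an overall precision and an average
  recall at each p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class EvaluationError(ValueError):
    """Invalid input to an evaluation routine."""


@dataclass(frozen=True)
class ConfusionCounts:
    """IDR-level TP/FP/TN/FN for one term classifier."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class TermMetrics:
    """Operating-point metrics for one (term, feature family) classifier."""

    term_id: str
    family: str
    sensitivity: float
    specificity: float
    precision: float
    mcc: float
    #: names of ratios whose denominator was zero (reported as 0)
    undefined: frozenset[str] = frozenset()


def _ratio(num: int, den: int) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def confusion_metrics(c: ConfusionCounts, term_id: str = "", family: str = "") -> TermMetrics:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP).

    Zero-denominator ratios are reported as 0 and flagged in ``undefined``.
    """
    if c.total == 0:
        raise EvaluationError("all-zero confusion counts")
    sens, u_sens = _ratio(c.tp, c.tp + c.fn)
    spec, u_spec = _ratio(c.tn, c.tn + c.fp)
    prec, u_prec = _ratio(c.tp, c.tp + c.fp)
    flags = frozenset(
        name
        for name, u in (("sensitivity", u_sens), ("specificity", u_spec), ("precision", u_prec))
        if u
    )
    return TermMetrics(term_id, family, sens, spec, prec, mcc(c), flags)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1]; 0 when any marginal is empty.

    ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``.
    """
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def better_than_random(m: TermMetrics) -> bool:
    """True iff the true positive rate exceeds the false positive rate."""
    return m.sensitivity > 1.0 - m.specificity


def average_over_terms(metrics: Sequence[TermMetrics]) -> dict[str, float]:
    """Unweighted means of sensitivity/specificity/precision/MCC over terms."""
    if not metrics:
        raise EvaluationError("no evaluated terms to average")
    return {
        "n_terms": float(len(metrics)),
        "sensitivity": float(np.mean([m.sensitivity for m in metrics])),
        "specificity": float(np.mean([m.specificity for m in metrics])),
        "precision": float(np.mean([m.precision for m in metrics])),
        "mcc": float(np.mean([m.mcc for m in metrics])),
    }


def metrics_table(metrics: Iterable[TermMetrics]) -> pd.DataFrame:
    rows = [
        {
            "term_id": m.term_id,
            "family": m.family,
            "sensitivity": m.sensitivity,
            "specificity": m.specificity,
            "precision": m.precision,
            "mcc": m.mcc,
            "undefined": ",".join(sorted(m.undefined)),
        }
        for m in metrics
    ]
    return pd.DataFrame(rows, columns=["term_id", "family", "sensitivity", "specificity", "precision", "mcc", "undefined"])


# ---------------------------------------------------------------------------
# per-IDR precision-recall protocol
# ---------------------------------------------------------------------------

DEFAULT_PROB_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 10))


@dataclass(frozen=True)
class PRCurve:
    """Overall precision / average recall over a posterior-threshold grid.

    ``points`` columns: p, n_correct, overall_precision, average_recall,
    average_precision (the mean of the per-IDR precisions, reported
    alongside the headline N_correct/N_total overall precision).
    """

    family: str
    points: pd.DataFrame
    test_set_size: int


def sample_test_set(
    idr_ids: Sequence[str], n: int = 105, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Uniform seeded sample of held-out IDR ids; returns (test, train)."""
    if n >= len(idr_ids):
        raise EvaluationError(f"test size n={n} must be < dataset size {len(idr_ids)}")
    rng = np.random.default_rng(seed)
    ids = list(idr_ids)
    test_idx = rng.choice(len(ids), size=n, replace=False)
    mask = np.zeros(len(ids), dtype=bool)
    mask[test_idx] = True
    test = [ids[i] for i in range(len(ids)) if mask[i]]
    train = [ids[i] for i in range(len(ids)) if not mask[i]]
    return test, train


def pr_analysis(
    predictions: pd.DataFrame,
    known_terms: Mapping[str, set[str]],
    prob_grid: Sequence[float] = DEFAULT_PROB_GRID,
    family: str = "",
) -> PRCurve:
    """Sweep the posterior threshold over the held-out IDRs.

    ``predictions`` has columns (idr_id, term_id, probability), one row per
    trained term classifier per test IDR. At each threshold p an IDR r
    predicts the term set S = {t : prob >= p}; against its known set K:

    * TP = |S & K|, FP = |S - K|, FN = |K - S|
    * per-IDR recall rho = TP/(TP+FN), precision pi = TP/(TP+FP) (0 when
      the denominator is empty)
    * overall precision at p = N_correct / N_total, where N_correct counts
      IDRs with TP >= 1
    * average recall at p = mean of rho over all test IDRs
    """
    idr_ids = sorted(known_terms)
    if not idr_ids:
        raise EvaluationError("empty test set")
    by_idr: dict[str, list[tuple[str, float]]] = {r: [] for r in idr_ids}
    for row in predictions.itertuples(index=False):
        if row.idr_id in by_idr:
            by_idr[row.idr_id].append((row.term_id, float(row.probability)))

    n_total = len(idr_ids)
    records = []
    for p in prob_grid:
        n_correct = 0
        recalls = []
        precisions = []
        for r in idr_ids:
            predicted = {t for t, prob in by_idr[r] if prob >= p}
            known = known_terms[r]
            tp = len(predicted & known)
            fp = len(predicted - known)
            fn = len(known - predicted)
            recalls.append(tp / (tp + fn) if tp + fn else 0.0)
            precisions.append(tp / (tp + fp) if tp + fp else 0.0)
            if tp >= 1:
                n_correct += 1
        records.append(
            {
                "p": float(p),
                "n_correct": n_correct,
                "overall_precision": n_correct / n_total,
                "average_recall": float(np.mean(recalls)),
                "average_precision": float(np.mean(precisions)),
            }
        )
    return PRCurve(family=family, points=pd.DataFrame(records), test_set_size=n_total)
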