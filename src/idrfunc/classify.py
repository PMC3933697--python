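"""One-vs-rest Gaussian Naive Bayes over IDR feature vectors.

The multi-label GO Slim problem is decomposed into one binary classifier per
term: an IDR is positive for term c if c (or its immediate ancestor, added by
annotation expansion) is in its parent protein's term set, negative otherwise.
Each classifier is a per-component Gaussian Naive Bayes fitted in log-space
with a variance floor, evaluated by seeded stratified 10-fold
cross-validation with an inclusive 0.5 posterior decision rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .evaluate import ConfusionCounts

logger = logging.getLogger("idrfunc")

#: relative variance floor: each class variance is raised to at least this
#: fraction of the component's global (pooled) variance
VAR_FLOOR_FACTOR = 1e-9
#: absolute floor keeping variances strictly positive for constant components
VAR_FLOOR_ABS = 1e-12
#: minimum positive IDRs for a term classifier to be trained at all
MIN_POSITIVES = 10
#: inclusive posterior operating point for calling a term present
DECISION_THRESHOLD = 0.5


class TermSkipped(RuntimeError):
    """A term classifier could not be trained/evaluated; carries the reason."""


@dataclass(frozen=True)
class TermAnnotation:
    """GO Slim term set carried by one IDR (copied from its parent protein)."""

    idr_id: str
    protein_id: str
    terms: frozenset[str]
    expanded: bool = False


def expand_annotations(terms: set[str] | frozenset[str], parent_map: Mapping[str, str]) -> frozenset[str]:
    """Add the immediate ancestor of every term that has one (single step).

    Terms without a parent entry pass through unchanged; the expansion is
    deliberately not transitive.
    """
    return frozenset(terms) | {parent_map[t] for t in terms if t in parent_map}


def expand_all(
    annotations: Sequence[TermAnnotation], parent_map: Mapping[str, str]
) -> list[TermAnnotation]:
    return [
        TermAnnotation(a.idr_id, a.protein_id, expand_annotations(a.terms, parent_map), True)
        for a in annotations
    ]


def binarize(
    annotations: Mapping[str, frozenset[str]], idr_ids: Sequence[str], term_id: str
) -> np.ndarray:
    """0/1 label vector over ``idr_ids``: 1 iff the IDR carries ``term_id``."""
    return np.array([1 if term_id in annotations[r] else 0 for r in idr_ids], dtype=int)


# ---------------------------------------------------------------------------
# Gaussian Naive Bayes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TermClassifier:
    """Per-component Gaussian class-conditionals and priors for one term."""

    term_id: str
    family: str
    mean_pos: np.ndarray
    var_pos: np.ndarray
    mean_neg: np.ndarray
    var_neg: np.ndarray
    prior_pos: float
    prior_neg: float
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        if np.any(self.var_pos <= 0) or np.any(self.var_neg <= 0):
            raise ValueError("class variances must be strictly positive")
        if abs(self.prior_pos + self.prior_neg - 1.0) > 1e-9:
            raise ValueError("class priors must sum to 1")


def train_term_classifier(
    X: np.ndarray,
    y: np.ndarray,
    term_id: str = "",
    family: str = "",
    var_floor_factor: float = VAR_FLOOR_FACTOR,
) -> TermClassifier:
    """Fit the two-class Gaussian NB with empirical priors and a variance floor.

    The floor is ``var_floor_factor`` times the global per-component variance
    (plus a tiny absolute term), so constant or near-constant components —
    common in sparse bigram vectors — cannot produce degenerate densities.
    Raises :class:`TermSkipped` if either class is absent.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    pos, neg = X[y == 1], X[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise TermSkipped(f"term {term_id!r}: single-class training set")
    floor = var_floor_factor * X.var(axis=0) + VAR_FLOOR_ABS
    return TermClassifier(
        term_id=term_id,
        family=family,
        mean_pos=pos.mean(axis=0),
        var_pos=np.maximum(pos.var(axis=0), floor),
        mean_neg=neg.mean(axis=0),
        var_neg=np.maximum(neg.var(axis=0), floor),
        prior_pos=len(pos) / len(X),
        prior_neg=len(neg) / len(X),
        n_pos=len(pos),
        n_neg=len(neg),
    )


def _log_joint(X: np.ndarray, mean: np.ndarray, var: np.ndarray, prior: float) -> np.ndarray:
    ll = -0.5 * (np.log(2 * np.pi * var) + (X - mean) ** 2 / var).sum(axis=1)
    return ll + np.log(prior)


def predict_proba(model: TermClassifier, X: np.ndarray) -> np.ndarray:
    """Posterior probability of the positive class, computed in log-space."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.mean_pos.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model family "
            f"{model.family!r} ({model.mean_pos.shape[0]})"
        )
    lp = _log_joint(X, model.mean_pos, model.var_pos, model.prior_pos)
    ln = _log_joint(X, model.mean_neg, model.var_neg, model.prior_neg)
    m = np.maximum(lp, ln)
    ep, en = np.exp(lp - m), np.exp(ln - m)
    return ep / (ep + en)


def predict_label(model: TermClassifier, X: np.ndarray) -> np.ndarray:
    """Inclusive 0.5 rule: posterior >= 0.5 calls the term present."""
    return (predict_proba(model, X) >= DECISION_THRESHOLD).astype(int)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def assign_folds(y: np.ndarray, k: int = 10, seed: int = 0) -> np.ndarray:
    """Stratified, seeded fold index (0..k-1) per sample."""
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        folds[test_idx] = f
    return folds


def cross_validate_term(
    X: np.ndarray,
    y: np.ndarray,
    term_id: str = "",
    family: str = "",
    k: int = 10,
    seed: int = 0,
    min_positives: int = MIN_POSITIVES,
) -> ConfusionCounts:
    """k-fold CV confusion counts for one term; every IDR scored exactly once.

    Raises :class:`TermSkipped` when the term has fewer than
    ``min_positives`` positive IDRs (or fewer positives than folds) or when
    any fold's training split is single-class.
    """
    y = np.asarray(y, dtype=int)
    n_pos = int(y.sum())
    if n_pos < min_positives:
        raise TermSkipped(f"term {term_id!r}: {n_pos} positives < min_positives={min_positives}")
    if n_pos < k or (len(y) - n_pos) < k:
        raise TermSkipped(f"term {term_id!r}: a class is smaller than k={k}")
    folds = assign_folds(y, k=k, seed=seed)
    tp = fp = tn = fn = 0
    for f in range(k):
        test = folds == f
        model = train_term_classifier(X[~test], y[~test], term_id, family)
        pred = predict_label(model, X[test])
        truth = y[test]
        tp += int(((pred == 1) & (truth == 1)).sum())
        fp += int(((pred == 1) & (truth == 0)).sum())
        tn += int(((pred == 0) & (truth == 0)).sum())
        fn += int(((pred == 0) & (truth == 1)).sum())
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def cross_validate_dataset(
    idr_ids: Sequence[str],
    X: np.ndarray,
    annotations: Mapping[str, frozenset[str]],
    terms: Sequence[str],
    family: str,
    k: int = 10,
    seed: int = 0,
    min_positives: int = MIN_POSITIVES,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """CV confusion counts for every term of one feature family.

    Returns the confusion table (term_id, family, tp, fp, tn, fn,
    n_train_pos) and the list of (term_id, reason) for skipped terms.
    """
    rows = []
    skipped: list[tuple[str, str]] = []
    for term in terms:
        y = binarize(annotations, idr_ids, term)
        try:
            c = cross_validate_term(X, y, term, family, k=k, seed=seed, min_positives=min_positives)
        except TermSkipped as e:
            logger.info("skipped: %s", e)
            skipped.append((term, str(e)))
            continue
        rows.append(
            {
                "term_id": term,
                "family": family,
                "tp": c.tp,
                "fp": c.fp,
                "tn": c.tn,
                "fn": c.fn,
                "n_train_pos": int(y.sum()),
            }
        )
    table = pd.DataFrame(rows, columns=["term_id", "family", "tp", "fp", "tn", "fn", "n_train_pos"])
    return table, skipped


def train_and_score(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    term_id: str = "",
    family: str = "",
    min_positives: int = MIN_POSITIVES,
) -> np.ndarray:
    """Train on the training split and return test posteriors (PR protocol)."""
    if int(np.sum(y_train)) < min_positives:
        raise TermSkipped(f"term {term_id!r}: fewer than {min_positives} training positives")
    model = train_term_classifier(X_train, y_train, term_id, family)
    return predict_proba(model, X_test)
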