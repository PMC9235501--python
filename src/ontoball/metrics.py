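"""CAFA-style evaluation of hierarchical multi-label function predictions.

Protein-centric metrics:

* ``Fmax`` — maximum over score thresholds ``t`` of the harmonic mean of
  precision (averaged over proteins with at least one predicted class at
  ``t``) and recall (averaged over all annotated proteins).
* ``Smin`` — minimum over ``t`` of ``sqrt(ru(t)^2 + mi(t)^2)`` where
  remaining uncertainty ``ru`` is the average summed information content
  of missed classes and misinformation ``mi`` that of wrongly predicted
  classes.
* ``AUPR`` — area under the precision-recall curve over pooled
  (protein, class) pairs, step-wise integration.

Class-centric metric:

* per-class ROC AUC over proteins, macro-averaged over classes that have
  at least one positive and one negative in the evaluation set
  (degenerate classes are excluded and their count logged).

Labels and predicted sets are assumed closed under subclass ancestors
(the true-path rule); propagation is the caller's responsibility.
Sub-ontology root classes are conventionally excluded from the evaluated
class list because propagation predicts them trivially.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = np.round(np.arange(0.0, 1.01, 0.01), 2)

#: Annotation-count bin edges for the per-specificity AUC breakdown.
DEFAULT_BIN_EDGES = (0, 10, 50, 100, 500, np.inf)


@dataclass
class EvaluationResult:
    fmax: float
    fmax_threshold: float
    smin: float
    aupr: float
    class_auc: dict[str, float]
    macro_auc: float
    coverage: float
    n_excluded_classes: int = 0
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "fmax": self.fmax, "fmax_threshold": self.fmax_threshold,
            "smin": self.smin, "aupr": self.aupr,
            "macro_auc": self.macro_auc, "coverage": self.coverage,
            "n_excluded_classes": self.n_excluded_classes,
        }

    def summary(self) -> str:
        rows = [("Fmax", f"{self.fmax:.3f} (t={self.fmax_threshold:.2f})"),
                ("Smin", f"{self.smin:.3f}"),
                ("AUPR", f"{self.aupr:.3f}"),
                ("macro AUC", f"{self.macro_auc:.3f} "
                              f"({len(self.class_auc)} classes)"),
                ("coverage", f"{self.coverage:.3f}")]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def _as_arrays(pred, labels=None):
    """Accept a PredictionMatrix-like object or plain arrays."""
    if labels is None:
        scores = np.asarray(pred.scores, dtype=float)
        labels = np.asarray(pred.labels, dtype=bool)
    else:
        scores = np.asarray(pred, dtype=float)
        labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError(f"score shape {scores.shape} != label shape {labels.shape}")
    return scores, labels


def fmax(pred, labels=None,
         thresholds: np.ndarray = DEFAULT_THRESHOLDS) -> tuple[float, float]:
    """CAFA protein-centric Fmax and its argmax threshold.

    At threshold ``t`` the predicted set of a protein is every class with
    score >= t.  Precision is averaged over proteins with a non-empty
    predicted set; recall over all annotated proteins.
    """
    scores, y = _as_arrays(pred, labels)
    annotated = y.any(axis=1)
    if not annotated.any():
        raise ValueError("no annotated protein in the evaluation set")
    scores, y = scores[annotated], y[annotated]
    best_f, best_t = 0.0, float(thresholds[0])
    npos = y.sum(axis=1)
    for t in thresholds:
        p = scores >= t
        tp = (p & y).sum(axis=1)
        npred = p.sum(axis=1)
        covered = npred > 0
        if not covered.any():
            continue
        prec = float(np.mean(tp[covered] / npred[covered]))
        rec = float(np.mean(tp / npos))
        if prec + rec == 0:
            continue
        f = 2 * prec * rec / (prec + rec)
        if f > best_f:
            best_f, best_t = f, float(t)
    return best_f, best_t


def smin(pred, labels=None, ic: Mapping[str, float] | Sequence[float] = None,
         class_ids: Sequence[str] | None = None,
         thresholds: np.ndarray = DEFAULT_THRESHOLDS) -> float:
    """CAFA Smin: minimal semantic distance sqrt(ru^2 + mi^2) over thresholds.

    ``ic`` is either a vector aligned with the score columns or a mapping
    from class id to information content (then ``class_ids`` aligns it).
    """
    scores, y = _as_arrays(pred, labels)
    if ic is None:
        raise ValueError("smin requires information-content values")
    if isinstance(ic, Mapping):
        if class_ids is None:
            raise ValueError("class_ids needed to align the IC mapping")
        missing = [c for c in class_ids if c not in ic]
        if missing:
            raise KeyError(f"no IC for classes: {missing[:5]}")
        icv = np.array([ic[c] for c in class_ids], dtype=float)
    else:
        icv = np.asarray(ic, dtype=float)
    if icv.shape[0] != scores.shape[1]:
        raise ValueError("IC vector length != number of classes")
    best = np.inf
    for t in thresholds:
        p = scores >= t
        ru = float(((~p & y) @ icv).mean())
        mi = float(((p & ~y) @ icv).mean())
        best = min(best, float(np.hypot(ru, mi)))
    return best


def aupr(pred, labels=None) -> float:
    """Area under the pooled precision-recall curve (step integration)."""
    scores, y = _as_arrays(pred, labels)
    yf = y.ravel()
    if not yf.any():
        raise ValueError("no positive (protein, class) pair")
    return float(average_precision_score(yf, scores.ravel()))


def class_centric_auc(pred, labels=None,
                      class_ids: Sequence[str] | None = None
                      ) -> tuple[dict[str, float], float]:
    """Per-class ROC AUC over proteins, plus the macro average.

    Classes that are all-positive or all-negative in the evaluation set
    cannot be ranked and are excluded (count logged).
    """
    scores, y = _as_arrays(pred, labels)
    k = scores.shape[1]
    ids = list(class_ids) if class_ids is not None else [str(i) for i in range(k)]
    if len(ids) != k:
        raise ValueError("class_ids length != number of score columns")
    out: dict[str, float] = {}
    excluded = 0
    for j, cid in enumerate(ids):
        col = y[:, j]
        if col.all() or not col.any():
            excluded += 1
            continue
        out[cid] = float(roc_auc_score(col, scores[:, j]))
    if excluded:
        logger.info("class_centric_auc: excluded %d degenerate classes", excluded)
    macro = float(np.mean(list(out.values()))) if out else float("nan")
    return out, macro


def auc_by_annotation_bin(class_auc: Mapping[str, float],
                          annotation_counts: Mapping[str, int],
                          bin_edges: Sequence[float] = DEFAULT_BIN_EDGES
                          ) -> pd.DataFrame:
    """Macro AUC per annotation-count bin (class specificity profile).

    Bins are ``[edge_i, edge_{i+1})``; a bin without classes is reported
    with NaN AUC rather than zero.
    """
    edges = list(bin_edges)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        members = [c for c in class_auc
                   if lo <= annotation_counts.get(c, 0) < hi]
        rows.append({
            "bin": f"[{lo:g}, {hi:g})",
            "n_classes": len(members),
            "macro_auc": float(np.mean([class_auc[c] for c in members]))
            if members else float("nan"),
        })
    return pd.DataFrame(rows)


def mean_ic_of_predictions(pred, class_ids: Sequence[str],
                           ic: Mapping[str, float], threshold: float,
                           labels=None) -> float:
    """Average IC over all predicted (protein, class) pairs at a threshold.

    Used with the Fmax-argmax threshold this measures how *specific* the
    predictions are: deeper, rarer classes carry more information.
    """
    scores = np.asarray(pred.scores if hasattr(pred, "scores") else pred,
                        dtype=float)
    icv = np.array([ic[c] for c in class_ids], dtype=float)
    mask = scores >= threshold
    if not mask.any():
        raise ValueError(f"no predictions at threshold {threshold}")
    return float((mask @ icv).sum() / mask.sum())


def coverage_at(pred, labels=None, threshold: float = 0.0) -> float:
    scores, _ = _as_arrays(pred, labels)
    return float(np.mean((scores >= threshold).any(axis=1)))


def evaluate_all(pred, labels=None, *, class_ids: Sequence[str],
                 ic: Mapping[str, float] | None = None,
                 exclude_classes: Sequence[str] = (),
                 thresholds: np.ndarray = DEFAULT_THRESHOLDS
                 ) -> EvaluationResult:
    """Full evaluation report over one prediction matrix.

    ``exclude_classes`` is typically the sub-ontology roots.  Smin is
    reported as NaN when no IC map is supplied.
    """
    scores, y = _as_arrays(pred, labels)
    keep = [j for j, c in enumerate(class_ids) if c not in set(exclude_classes)]
    ids = [class_ids[j] for j in keep]
    scores, y = scores[:, keep], y[:, keep]
    f, t = fmax(scores, y, thresholds)
    s = smin(scores, y, ic=ic, class_ids=ids, thresholds=thresholds) \
        if ic is not None else float("nan")
    try:
        pr = aupr(scores, y)
    except ValueError:
        pr = float("nan")
    per_class, macro = class_centric_auc(scores, y, ids)
    return EvaluationResult(
        fmax=f, fmax_threshold=t, smin=s, aupr=pr,
        class_auc=per_class, macro_auc=macro,
        coverage=coverage_at(scores, y, t),
        n_excluded_classes=len(class_ids) - len(ids),
    )
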