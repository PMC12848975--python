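"""Evaluation of multilabel GO predictions: protein-centric Fmax, AUPR, AUC.

Fmax is the CAFA-style protein-centric statistic: sweep a score threshold t
over {0.01, ..., 1.00}; at each t precision is averaged over proteins that
predict at least one term at that threshold, recall is averaged over all
proteins with at least one true label, and Fmax is the maximum harmonic mean
over the sweep. AUPR is micro-averaged over all protein-term pairs with the
non-interpolated step rule; AUC is the term-centric ROC area (midrank tie
handling) macro-averaged over terms that have both a positive and a negative
protein. The averaging modes are configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

DEFAULT_THRESHOLDS = np.round(np.arange(0.01, 1.0 + 1e-9, 0.01), 2)


class UndefinedMetricError(ValueError):
    """Raised when truth is too degenerate for the metric to be defined."""


@dataclass(frozen=True)
class EvalReport:
    """One branch's evaluation summary."""

    fmax: float
    fmax_threshold: float
    aupr: float
    auc: float
    branch: str = ""
    n_proteins: int = 0
    n_terms: int = 0

    def __post_init__(self) -> None:
        for name in ("fmax", "aupr", "auc"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    def format_table(self) -> str:
        header = f"{'branch':<8}{'Fmax':>8}{'AUC':>8}{'AUPR':>8}"
        row = (
            f"{self.branch or '-':<8}{self.fmax:>8.3f}"
            f"{self.auc:>8.3f}{self.aupr:>8.3f}"
        )
        return header + "\n" + row


def _check_aligned(preds: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    preds = np.asarray(preds, dtype=float)
    truth = np.asarray(truth)
    if preds.shape != truth.shape or preds.ndim != 2:
        raise ValueError("predictions and truth must be aligned P×L matrices")
    if not np.all(np.isfinite(preds)):
        raise ValueError("predictions must be finite")
    return preds, truth.astype(np.int8)


def fmax(
    preds: np.ndarray,
    truth: np.ndarray,
    thresholds: np.ndarray = DEFAULT_THRESHOLDS,
) -> tuple[float, float]:
    """Protein-centric Fmax and its optimal threshold (lowest t on ties).

    precision(t) averages TP/predicted over proteins with ≥1 prediction ≥ t;
    recall(t) averages TP/true over all proteins with ≥1 true label;
    F(t) = 2pr/(p+r) with 0/0 → 0.
    """
    preds, truth = _check_aligned(preds, truth)
    has_true = truth.sum(axis=1) > 0
    if not has_true.any():
        raise UndefinedMetricError("no protein has a positive label")

    best_f, best_t = 0.0, float(thresholds[0])
    for t in thresholds:
        predicted = preds >= t
        n_pred = predicted.sum(axis=1)
        tp = (predicted & (truth == 1)).sum(axis=1)

        covered = n_pred > 0
        precision = float((tp[covered] / n_pred[covered]).mean()) if covered.any() else 0.0
        recall = float((tp[has_true] / truth[has_true].sum(axis=1)).mean())
        f = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
        if f > best_f + 1e-15:
            best_f, best_t = f, float(t)
    return best_f, best_t


def aupr(preds: np.ndarray, truth: np.ndarray, average: str = "micro") -> float:
    """Area under the precision-recall curve (non-interpolated step rule).

    ``micro`` pools all protein-term cells into one curve; ``macro`` averages
    per-term areas over terms with at least one positive. Tied scores are
    handled as blocks (one curve point per distinct score).
    """
    preds, truth = _check_aligned(preds, truth)
    flat_t = truth.ravel()
    if flat_t.min() == flat_t.max():
        raise UndefinedMetricError("truth has no positive or no negative cell")
    if average == "micro":
        return float(average_precision_score(flat_t, preds.ravel()))
    if average == "macro":
        per_term = [
            average_precision_score(truth[:, j], preds[:, j])
            for j in range(truth.shape[1])
            if truth[:, j].any()
        ]
        if not per_term:
            raise UndefinedMetricError("no term has a positive protein")
        return float(np.mean(per_term))
    raise ValueError("average must be 'micro' or 'macro'")


def auc(preds: np.ndarray, truth: np.ndarray, average: str = "macro") -> float:
    """ROC area with midrank tie handling.

    ``macro`` averages per-term ROC AUC over terms having both classes;
    ``micro`` pools all cells into a single curve.
    """
    preds, truth = _check_aligned(preds, truth)
    if average == "micro":
        flat_t = truth.ravel()
        if flat_t.min() == flat_t.max():
            raise UndefinedMetricError("truth has no positive or no negative cell")
        return float(roc_auc_score(flat_t, preds.ravel()))
    if average == "macro":
        per_term = [
            roc_auc_score(truth[:, j], preds[:, j])
            for j in range(truth.shape[1])
            if 0 < truth[:, j].sum() < truth.shape[0]
        ]
        if not per_term:
            raise UndefinedMetricError("no term has both a positive and a negative")
        return float(np.mean(per_term))
    raise ValueError("average must be 'micro' or 'macro'")


def evaluate(
    preds: np.ndarray,
    truth: np.ndarray,
    branch: str = "",
    aupr_average: str = "micro",
    auc_average: str = "macro",
) -> EvalReport:
    """Compute all three metrics on aligned prediction/label matrices."""
    f, t = fmax(preds, truth)
    return EvalReport(
        fmax=f,
        fmax_threshold=t,
        aupr=aupr(preds, truth, average=aupr_average),
        auc=auc(preds, truth, average=auc_average),
        branch=branch,
        n_proteins=int(preds.shape[0]),
        n_terms=int(preds.shape[1]),
    )


def read_prediction_tsv(path, proteins, terms) -> np.ndarray:
    """Read a (protein_id, term_id, score) TSV into an aligned P×L matrix."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", names=["protein_id", "term_id", "score"],
                     comment="#", dtype={"score": float})
    pi = {p: i for i, p in enumerate(proteins)}
    ti = {t: j for j, t in enumerate(terms)}
    mat = np.zeros((len(proteins), len(terms)))
    for p, t, s in df.itertuples(index=False):
        if p in pi and t in ti:
            mat[pi[p], ti[t]] = s
    return mat
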