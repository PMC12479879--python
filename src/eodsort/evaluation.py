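"""Performance metrics, prediction/truth alignment, body-parameter analysis.

Cluster ids are nominal, so predicted labels are aligned to the truth by
the better of the two label permutations before accuracy and the Matthews
correlation coefficient (MCC) are computed. MCC is preferred here because
dyad recordings are often unbalanced (one fish may discharge far more than
the other). Running time per classified EOD is reported for bookkeeping
only; it is hardware-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, ShapeError
from .io_core import EODEvent


@dataclass
class EvalResult:
    """Aligned accuracy, MCC, normalized runtime and the confusion matrix."""

    acc: float
    mcc: float
    rt_ms_per_eod: float
    confusion: np.ndarray
    alignment: dict
    n_matched: int
    n_unmatched_pred: int = 0
    n_unmatched_truth: int = 0


def align_labels(pred, truth) -> tuple[np.ndarray, dict]:
    """Best of the two label permutations mapping pred onto truth's labels.

    Returns the aligned prediction array (in truth's label alphabet) and the
    chosen mapping. Aligned accuracy is >= 0.5 by construction.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ShapeError("pred and truth must have equal length")
    pred_ids = list(np.unique(pred))
    truth_ids = list(np.unique(truth))
    if len(pred_ids) > 2 or len(truth_ids) > 2:
        raise DomainError("alignment is defined for two-class labels")
    while len(truth_ids) < 2:
        truth_ids.append(truth_ids[0])
    best_map, best_acc = None, -1.0
    candidates = [dict(zip(pred_ids, truth_ids)),
                  dict(zip(pred_ids, truth_ids[::-1]))]
    for mapping in candidates:
        aligned = np.array([mapping[p] for p in pred])
        acc = float(np.mean(aligned == truth))
        if acc > best_acc:
            best_acc, best_map = acc, mapping
    aligned = np.array([best_map[p] for p in pred])
    return aligned, best_map


def confusion_2x2(pred, truth) -> np.ndarray:
    """2 x 2 confusion counts with classes in sorted truth order."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    classes = sorted(set(np.unique(truth)) | set(np.unique(pred)))
    if len(classes) > 2:
        raise DomainError("expected a two-class problem")
    while len(classes) < 2:
        classes.append(f"{classes[0]}_other")
    out = np.zeros((2, 2), dtype=np.int64)
    for i, a in enumerate(classes):
        for j, b in enumerate(classes):
            out[i, j] = int(np.sum((truth == a) & (pred == b)))
    return out


def mcc(confusion: np.ndarray) -> float:
    """Matthews correlation coefficient of a 2 x 2 confusion matrix.

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); a zero factor in
    the denominator yields 0 by convention.
    """
    c = np.asarray(confusion, dtype=np.int64)
    if c.shape != (2, 2):
        raise ShapeError("confusion matrix must be 2 x 2")
    if np.any(c < 0):
        raise DomainError("confusion counts must be nonnegative")
    tp, fn = int(c[0, 0]), int(c[0, 1])
    fp, tn = int(c[1, 0]), int(c[1, 1])
    denom_factors = [tp + fp, tp + fn, tn + fp, tn + fn]
    if any(f == 0 for f in denom_factors):
        return 0.0
    num = tp * tn - fp * fn
    return float(num / np.sqrt(np.prod([float(f) for f in denom_factors])))


def match_events(pred_events: list[EODEvent], truth_events: list[EODEvent],
                 tol_s: float = 2e-5) -> list[tuple[int, int]]:
    """Greedy nearest-time 1:1 matching of events within ``tol_s`` seconds."""
    pairs = []
    used: set[int] = set()
    truth_times = np.array([e.t_s for e in truth_events])
    order = np.argsort(truth_times)
    for i, e in enumerate(pred_events):
        pos = np.searchsorted(truth_times[order], e.t_s)
        best, best_dt = -1, tol_s * (1 + 1e-9)
        for j in (pos - 1, pos, pos + 1):
            if 0 <= j < order.size and int(order[j]) not in used:
                dt = abs(truth_times[order[j]] - e.t_s)
                if dt <= best_dt:
                    best, best_dt = int(order[j]), dt
        if best >= 0:
            pairs.append((i, best))
            used.add(best)
    return pairs


def evaluate_run(pred_events: list[EODEvent], truth_events: list[EODEvent],
                 elapsed_s: float, tol_s: float = 2e-5) -> EvalResult:
    """Score a labeled run against ground truth.

    Events are matched 1:1 by nearest time within ``tol_s`` (one sample at
    50 kHz by default); unmatched events on either side are excluded from
    the confusion matrix but counted in the result. For supervised runs,
    ``elapsed_s`` should include training time.
    """
    pairs = match_events(pred_events, truth_events, tol_s)
    if not pairs:
        raise DomainError("no events matched between prediction and truth")
    pred = np.array([pred_events[i].label for i, _ in pairs])
    truth = np.array([truth_events[j].truth for _, j in pairs])
    aligned, mapping = align_labels(pred, truth)
    confusion = confusion_2x2(aligned, truth)
    acc = float(np.trace(confusion) / confusion.sum())
    return EvalResult(
        acc=acc, mcc=mcc(confusion),
        rt_ms_per_eod=1e3 * elapsed_s / len(pred_events),
        confusion=confusion, alignment=mapping, n_matched=len(pairs),
        n_unmatched_pred=len(pred_events) - len(pairs),
        n_unmatched_truth=len(truth_events) - len(pairs),
    )


def body_param_correlation(per_dyad_metrics: pd.DataFrame,
                           body_deltas: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and two-sided p for each (metric, body-difference) pair.

    ``per_dyad_metrics`` holds one row per dyad (e.g. columns acc, mcc);
    ``body_deltas`` the per-dyad absolute body-parameter differences
    (e.g. delta_weight_g, delta_total_length_cm, delta_standard_length_cm).
    Zero-variance columns yield missing entries rather than errors. The
    p-values come from the standard t transform of r with n - 2 degrees of
    freedom; no multiplicity correction is applied.
    """
    if len(per_dyad_metrics) != len(body_deltas):
        raise ShapeError("metrics and body tables must have equal rows")
    if len(per_dyad_metrics) < 3:
        raise DomainError("need at least 3 dyads for a correlation")
    rows = []
    for metric in per_dyad_metrics.columns:
        for delta in body_deltas.columns:
            x = per_dyad_metrics[metric].to_numpy(dtype=float)
            y = body_deltas[delta].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x, y)
            rows.append({"metric": metric, "delta": delta,
                         "r": float(r) if np.isfinite(r) else np.nan,
                         "p": float(p) if np.isfinite(p) else np.nan})
    return pd.DataFrame(rows)
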