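"""Scoring deletion calls against a truth set.

Calls match truth records when both breakpoints agree within a tolerance
(circular distance on the mtDNA circle); matching is greedy one-to-one.
Without an explicit negative set, accuracy takes the Jaccard form
tp / (tp + fp + fn); with negatives the standard four-term form is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

DEFAULT_TOLERANCE_BP = 10


@dataclass
class BenchmarkResult:
    tp: int
    fp: int
    fn: int
    tn: Optional[int]
    recall: float
    precision: float
    accuracy: float
    f1: float
    heteroplasmy_mae: Optional[float] = None
    undefined_metrics: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        d = {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "recall": self.recall, "precision": self.precision,
            "accuracy": self.accuracy, "f1": self.f1,
            "heteroplasmy_mae": self.heteroplasmy_mae,
        }
        return d


def _circ_dist(a: int, b: int, L: int) -> int:
    d = abs(a - b) % L
    return min(d, L - d)


def _junction_distance(call, truth, L: int) -> tuple[int, int]:
    return (
        _circ_dist(call.del_start, truth.del_start, L),
        _circ_dist(call.del_end, truth.del_end, L),
    )


def match_calls(
    calls: Sequence,
    truth: Sequence,
    tolerance_bp: int = DEFAULT_TOLERANCE_BP,
    L: int = 16_300,
) -> tuple[int, int, int, list[tuple[int, int]]]:
    """Optimal one-to-one matching of calls to truth records.

    A call may match a truth record iff both breakpoint distances
    (circular) are within ``tolerance_bp``. Among all one-to-one
    assignments the one maximizing the number of matches (and, among
    those, minimizing total breakpoint distance) is chosen, so the result
    does not depend on call order. Returns (tp, fp, fn, matched index
    pairs (call_idx, truth_idx)).
    """
    from scipy.optimize import linear_sum_assignment

    if tolerance_bp < 0:
        raise ValueError("tolerance_bp must be >= 0")
    n_c, n_t = len(calls), len(truth)
    if n_c == 0 or n_t == 0:
        return 0, n_c, n_t, []
    # forbidden pairs get a cost exceeding any achievable total distance
    big = 4 * (tolerance_bp + 1) * (min(n_c, n_t) + 1)
    import numpy as np

    cost = np.full((n_c, n_t), float(big))
    for ci, c in enumerate(calls):
        for ti, t in enumerate(truth):
            d1, d2 = _junction_distance(c, t, L)
            if d1 <= tolerance_bp and d2 <= tolerance_bp:
                cost[ci, ti] = d1 + d2
    rows, cols = linear_sum_assignment(cost)
    pairs = [
        (int(ci), int(ti))
        for ci, ti in zip(rows, cols)
        if cost[ci, ti] < big
    ]
    pairs.sort()
    tp = len(pairs)
    return tp, n_c - tp, n_t - tp, pairs


def compute_metrics(
    tp: int,
    fp: int,
    fn: int,
    tn: Optional[int] = None,
    heteroplasmy_mae: Optional[float] = None,
) -> BenchmarkResult:
    """Recall, precision, accuracy and F1 from confusion counts.

    Zero-denominator metrics are reported as 0 and flagged in
    ``undefined_metrics``.
    """
    if min(tp, fp, fn) < 0 or (tn is not None and tn < 0):
        raise ValueError("counts must be non-negative")
    undefined = []

    def _ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    recall = _ratio(tp, tp + fn, "recall")
    precision = _ratio(tp, tp + fp, "precision")
    if tn is None:
        accuracy = _ratio(tp, tp + fp + fn, "accuracy")
    else:
        accuracy = _ratio(tp + tn, tp + tn + fp + fn, "accuracy")
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        undefined.append("f1")
        f1 = 0.0
    return BenchmarkResult(
        tp=tp, fp=fp, fn=fn, tn=tn,
        recall=recall, precision=precision, accuracy=accuracy, f1=f1,
        heteroplasmy_mae=heteroplasmy_mae,
        undefined_metrics=tuple(undefined),
    )


def score_calls(
    calls: Sequence,
    truth: Sequence,
    tolerance_bp: int = DEFAULT_TOLERANCE_BP,
    L: int = 16_300,
    truth_heteroplasmy: Optional[Sequence[float]] = None,
) -> BenchmarkResult:
    """match_calls + compute_metrics, with optional heteroplasmy MAE over TPs."""
    tp, fp, fn, pairs = match_calls(calls, truth, tolerance_bp, L)
    mae = None
    if truth_heteroplasmy is not None and pairs:
        errs = [
            abs(calls[ci].f - truth_heteroplasmy[ti]) for ci, ti in pairs
        ]
        mae = sum(errs) / len(errs)
    return compute_metrics(tp, fp, fn, heteroplasmy_mae=mae)
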