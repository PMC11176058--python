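"""Evaluation helpers against simulator ground truth."""

from __future__ import annotations

import numpy as np


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Overlap as a fraction of the longer interval (0 when disjoint)."""
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return ov / max(a[1] - a[0], b[1] - b[0])


def match_intervals(
    truth: list[tuple[int, int]],
    called: list[tuple[int, int]],
    min_reciprocal: float = 0.5,
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of called to truth intervals.

    A pair matches when the overlap is at least ``min_reciprocal`` of both
    interval lengths.  Returns (true positives, false positives, false
    negatives).
    """
    truth = sorted(truth)
    called = sorted(called)
    used = np.zeros(len(truth), dtype=bool)
    tp = 0
    for c in called:
        best, best_ov = None, 0.0
        for i, t in enumerate(truth):
            if used[i]:
                continue
            if t[0] >= c[1]:
                break
            ov = min(c[1], t[1]) - max(c[0], t[0])
            if ov <= 0:
                continue
            if ov >= min_reciprocal * (c[1] - c[0]) and ov >= min_reciprocal * (t[1] - t[0]):
                if ov > best_ov:
                    best, best_ov = i, ov
        if best is not None:
            used[best] = True
            tp += 1
    fp = len(called) - tp
    fn = len(truth) - tp
    return tp, fp, fn


def f1_score(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings (delegates to sklearn)."""
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(labels_a, labels_b))
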