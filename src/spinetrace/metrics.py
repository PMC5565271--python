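"""Segmentation and detection scoring against ground truth.

Dendrite masks are scored on a pixel basis (precision/recall plus rates
normalized by the ground-truth pixel count). Spine detections are scored
object-wise: predicted and true masks are matched greedily one-to-one by
descending overlap, and a true spine counts as detected when the matched
prediction covers at least half of it.
"""

from __future__ import annotations

import numpy as np

__all__ = ["pixel_metrics", "detection_metrics", "mask_jaccard"]


def mask_jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two boolean masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum()) / float(union)


def pixel_metrics(predicted: np.ndarray, truth: np.ndarray) -> dict:
    """Pixel-level precision/recall and truth-normalized TP/FP/FN rates."""
    predicted = np.asarray(predicted, bool)
    truth = np.asarray(truth, bool)
    if predicted.shape != truth.shape:
        raise ValueError("masks must have equal dimensions")
    n_truth = int(truth.sum())
    if n_truth == 0:
        raise ValueError("empty ground truth; recall is undefined")
    tp = int(np.logical_and(predicted, truth).sum())
    fp = int(np.logical_and(predicted, ~truth).sum())
    fn = n_truth - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    return dict(
        precision=precision,
        recall=tp / n_truth,
        tp_rate=tp / n_truth,
        fp_rate=fp / n_truth,
        fn_rate=fn / n_truth,
    )


def _coverage(pred: np.ndarray, true: np.ndarray) -> float:
    n_true = true.sum()
    if n_true == 0:
        return 0.0
    return float(np.logical_and(pred, true).sum()) / float(n_true)


def detection_metrics(
    predicted: list[np.ndarray],
    truth: list[np.ndarray],
    overlap_min: float = 0.5,
    use_jaccard: bool = False,
) -> dict:
    """Object-level detection precision and recall.

    Greedy one-to-one matching by descending overlap; a true spine is
    detected iff its match covers at least ``overlap_min`` of it (coverage
    of ground truth by default, Jaccard if ``use_jaccard``).
    """
    score = mask_jaccard if use_jaccard else _coverage
    pairs = []
    for pi, pred in enumerate(predicted):
        for ti, true in enumerate(truth):
            ov = score(np.asarray(pred, bool), np.asarray(true, bool))
            if ov > 0:
                pairs.append((ov, pi, ti))
    pairs.sort(key=lambda t: -t[0])
    used_p, used_t = set(), set()
    n_detected = 0
    for ov, pi, ti in pairs:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
        if ov >= overlap_min:
            n_detected += 1
    recall = n_detected / len(truth) if truth else float("nan")
    precision = n_detected / len(predicted) if predicted else float("nan")
    return dict(
        precision=precision,
        recall=recall,
        n_detected=n_detected,
        n_truth=len(truth),
        n_predicted=len(predicted),
    )
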