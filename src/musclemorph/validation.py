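"""Segmentation/typing validation against ground truth label maps.

Used by the test-bench: matches predicted fibers to truth fibers by overlap
and reports recall, per-fiber IoU and CSA error.  A truth fiber counts as
recovered when some predicted fiber overlaps it with IoU >= ``iou_cutoff``
(one-to-one, greedy on IoU).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MatchResult:
    n_truth: int
    n_pred: int
    #: rows (truth_id, pred_id, iou) for matched pairs
    matches: np.ndarray

    @property
    def recall(self) -> float:
        return len(self.matches) / self.n_truth if self.n_truth else 0.0

    @property
    def mean_iou(self) -> float:
        return float(self.matches[:, 2].mean()) if len(self.matches) else 0.0


def match_fibers(truth_labels: np.ndarray, pred_labels: np.ndarray,
                 iou_cutoff: float = 0.5) -> MatchResult:
    """Greedy one-to-one matching of predicted to truth regions by IoU."""
    truth_labels = np.asarray(truth_labels)
    pred_labels = np.asarray(pred_labels)
    if truth_labels.shape != pred_labels.shape:
        raise ValueError("label maps must share dimensions")
    n_t = int(truth_labels.max())
    n_p = int(pred_labels.max())
    if n_t == 0 or n_p == 0:
        return MatchResult(n_t, n_p, np.empty((0, 3)))

    t_flat = truth_labels.ravel().astype(np.int64)
    p_flat = pred_labels.ravel().astype(np.int64)
    both = (t_flat > 0) & (p_flat > 0)
    pair = t_flat[both] * (n_p + 1) + p_flat[both]
    pair_ids, inter = np.unique(pair, return_counts=True)
    t_ids = pair_ids // (n_p + 1)
    p_ids = pair_ids % (n_p + 1)

    area_t = np.bincount(t_flat, minlength=n_t + 1)
    area_p = np.bincount(p_flat, minlength=n_p + 1)
    union = area_t[t_ids] + area_p[p_ids] - inter
    iou = inter / union

    order = np.argsort(-iou)
    used_t = np.zeros(n_t + 1, bool)
    used_p = np.zeros(n_p + 1, bool)
    matches = []
    for idx in order:
        if iou[idx] < iou_cutoff:
            break
        t, p = t_ids[idx], p_ids[idx]
        if used_t[t] or used_p[p]:
            continue
        used_t[t] = used_p[p] = True
        matches.append((t, p, iou[idx]))
    return MatchResult(n_t, n_p, np.array(matches).reshape(-1, 3))


def csa_errors(result: MatchResult, truth_labels: np.ndarray,
               pred_labels: np.ndarray) -> np.ndarray:
    """Per-matched-fiber relative CSA error |pred - truth| / truth."""
    if len(result.matches) == 0:
        return np.empty(0)
    area_t = np.bincount(truth_labels.ravel())
    area_p = np.bincount(pred_labels.ravel())
    t = result.matches[:, 0].astype(int)
    p = result.matches[:, 1].astype(int)
    return np.abs(area_p[p] - area_t[t]) / area_t[t]


def typing_error_rate(result: MatchResult, truth_types: list[str],
                      pred_types: list[str]) -> float:
    """Fraction of matched fibers whose type call disagrees with truth."""
    if len(result.matches) == 0:
        return 0.0
    wrong = 0
    for t, p, _ in result.matches:
        if truth_types[int(t) - 1] != pred_types[int(p) - 1]:
            wrong += 1
    return wrong / len(result.matches)
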