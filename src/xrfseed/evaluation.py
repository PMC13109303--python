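"""Segmentation scoring (IoU, Dice) and agreement statistics.

Whole-image scores treat the union of object pixels as one foreground set;
per-object scores greedily match predicted to truth objects by descending
pairwise IoU, one-to-one. For masks built on the same pixel grid the two
coefficients obey Dice = 2*IoU / (1 + IoU). Percentages are fractions x100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, DimensionMismatchError


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise DimensionMismatchError(f"mask grids differ: {a.shape} vs {b.shape}")
    return a, b


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union; defined as 1.0 when both masks are empty."""
    a, b = _check_pair(a, b)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B|/(|A|+|B|); 1.0 when both masks are empty."""
    a, b = _check_pair(a, b)
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / total)


@dataclass
class EvalResult:
    """Whole-image and per-object agreement between two label maps."""

    iou_pct: float
    dice_pct: float
    matches: list[tuple[int, int, float]] = field(default_factory=list)
    unmatched_pred: list[int] = field(default_factory=list)
    unmatched_truth: list[int] = field(default_factory=list)
    object_dice_pct: float = 0.0   # mean over truth objects; unmatched score 0
    both_empty: bool = False


def match_and_score(pred: np.ndarray, truth: np.ndarray) -> EvalResult:
    """Score a predicted label map against ground truth.

    Whole-image IoU/Dice use the foreground unions. Object matching is greedy
    on descending pairwise IoU (ties by label values), one-to-one; leftover
    objects are reported as unmatched (splits/merges).
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise DimensionMismatchError(f"grids differ: {pred.shape} vs {truth.shape}")

    fg_iou = iou(pred > 0, truth > 0)
    fg_dice = dice(pred > 0, truth > 0)
    both_empty = pred.max() == 0 and truth.max() == 0

    pred_areas = np.bincount(pred.ravel())
    truth_areas = np.bincount(truth.ravel())
    overlap_pairs: dict[tuple[int, int], int] = {}
    sel = (pred > 0) & (truth > 0)
    if sel.any():
        pairs, counts = np.unique(
            np.stack([pred[sel], truth[sel]]), axis=1, return_counts=True
        )
        for (p, t), n in zip(pairs.T, counts):
            overlap_pairs[(int(p), int(t))] = int(n)

    candidates = []
    for (p, t), inter in overlap_pairs.items():
        union = pred_areas[p] + truth_areas[t] - inter
        candidates.append((inter / union, p, t, inter))
    candidates.sort(key=lambda x: (-x[0], x[1], x[2]))

    used_p: set[int] = set()
    used_t: set[int] = set()
    matches = []
    object_dice: dict[int, float] = {}
    for score, p, t, inter in candidates:
        if p in used_p or t in used_t:
            continue
        used_p.add(p)
        used_t.add(t)
        matches.append((p, t, float(score)))
        object_dice[t] = 2.0 * inter / (pred_areas[p] + truth_areas[t])

    all_p = [int(v) for v in np.unique(pred) if v > 0]
    all_t = [int(v) for v in np.unique(truth) if v > 0]
    per_truth = [object_dice.get(t, 0.0) for t in all_t]
    return EvalResult(
        iou_pct=100.0 * fg_iou,
        dice_pct=100.0 * fg_dice,
        matches=matches,
        unmatched_pred=[p for p in all_p if p not in used_p],
        unmatched_truth=[t for t in all_t if t not in used_t],
        object_dice_pct=100.0 * float(np.mean(per_truth)) if per_truth else 0.0,
        both_empty=both_empty,
    )


def agreement(x, y) -> tuple[float, float]:
    """Pearson correlation and its square between two trait vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise DegenerateInputError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance: correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    return r, r * r
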