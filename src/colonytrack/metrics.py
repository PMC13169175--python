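"""Evaluation metrics: tracklet-level F1 for tracking, assignment
accuracy for lineage tracing.

A *tracklet* is one cell's correspondence between two consecutive frames.
Predicted and ground-truth movies must contain identical cell footprints
(tracking only relabels); cells are matched across the two movies by
exact pixel-set equality. Per transition, scoring is restricted to cells
that have a ground-truth correspondence: TP are predicted assignments
that equal the truth, FN truth assignments missed or contradicted, FP
predicted assignments (within the restricted set) that are not in the
truth. F1 is computed per transition and reported as mean +- standard
error of the mean over transitions; transitions with no ground-truth
assignment at all are skipped.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .mask_io import LineageTable, MaskMovie

__all__ = ["TrackletScore", "tracklet_f1", "lineage_accuracy",
           "FootprintMismatchError"]


class FootprintMismatchError(ValueError):
    pass


@dataclasses.dataclass
class TrackletScore:
    per_transition: list[tuple[int, int, int]]   # (TP, FP, FN)
    f1_per_transition: list[float]
    mean_f1: float
    sem_f1: float

    def summary(self) -> str:
        return (f"tracklet F1 = {self.mean_f1:.4f} +- {self.sem_f1:.4f} "
                f"(SEM over {len(self.f1_per_transition)} transitions)")


def _footprint_map(pred: np.ndarray, truth: np.ndarray) -> dict[int, int]:
    """truth label -> predicted label, requiring identical footprints."""
    if pred.shape != truth.shape or \
            not ((pred > 0) == (truth > 0)).all():
        raise FootprintMismatchError("foreground masks differ")
    mapping: dict[int, int] = {}
    for lab in np.unique(truth):
        if lab == 0:
            continue
        sel = truth == lab
        plabs = np.unique(pred[sel])
        if len(plabs) != 1:
            raise FootprintMismatchError(
                f"truth cell {lab} covered by several predicted labels")
        plab = int(plabs[0])
        if np.count_nonzero(pred == plab) != np.count_nonzero(sel):
            raise FootprintMismatchError(
                f"truth cell {lab} and predicted cell {plab} footprints differ")
        mapping[int(lab)] = plab
    return mapping


def tracklet_f1(predicted: MaskMovie, truth: MaskMovie) -> TrackletScore:
    """Tracklet F1 of a predicted (relabeled) movie against ground truth."""
    if len(predicted) != len(truth):
        raise FootprintMismatchError("movies differ in frame count")
    maps = [_footprint_map(p.labels, t.labels)
            for p, t in zip(predicted.frames, truth.frames)]
    counts, f1s = [], []
    for t in range(len(truth) - 1):
        ids_a = set(maps[t])
        ids_b = set(maps[t + 1])
        survivors = ids_a & ids_b          # truth: label persists => same cell
        if not survivors:
            continue
        inv_b = {p: lab for lab, p in maps[t + 1].items()}
        tp = fp = 0
        for x in survivors:
            y = inv_b.get(maps[t][x])      # predicted partner of x, if any
            if y == x:
                tp += 1
            elif y is not None:
                fp += 1
        fn = len(survivors) - tp
        counts.append((tp, fp, fn))
        f1s.append(2 * tp / (2 * tp + fp + fn) if tp else 0.0)
    mean = float(np.mean(f1s)) if f1s else 0.0
    sem = float(np.std(f1s, ddof=1) / np.sqrt(len(f1s))) if len(f1s) > 1 else 0.0
    return TrackletScore(counts, f1s, mean, sem)


def lineage_accuracy(predicted: LineageTable, truth: LineageTable,
                     count_unassignable: bool = True) -> float:
    """Fraction of ground-truth buds whose predicted mother is correct.

    Buds absent from the prediction count as incorrect by default; with
    ``count_unassignable=False`` they are dropped from the denominator.
    """
    if len(truth) == 0:
        raise ValueError("empty ground-truth lineage table")
    pred = {int(r.bud_id): int(r.mother_id) for r in predicted}
    correct = total = 0
    for row in truth:
        p = pred.get(int(row.bud_id))
        if p is None and not count_unassignable:
            continue
        total += 1
        if p == int(row.mother_id):
            correct += 1
    return correct / total if total else 0.0
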