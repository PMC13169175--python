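"""Global frame-to-frame assignment from per-pair scores.

The network's correct-class node scores are reshaped into an n1 x n2
score matrix (frame-t cells x frame-t+1 cells; pairs pruned from the
graph keep a floor score of 0). Budding yeast uses a plain linear sum
assignment (Jonker-Volgenant, via scipy) maximizing total score, after
which matches below a confidence threshold are severed into a lost +
new cell pair. Fission yeast divides symmetrically, retiring the parent
label: with m cells in frame t and n > m in frame t+1, at most n - m
cells divided, so at most 2m - n cells may be tracked through; this
match-count cap turns the problem into a small binary program, solved
exactly with scipy's HiGHS-backed MILP.

``track_movie`` runs the whole pipeline over a movie: features -> graph
-> network scores -> solve -> relabel, propagating labels frame to frame
and logging every new cell, lost cell, and (in fission mode) division.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import optimize

from .features import FrameGeometry
from .graph import (DEFAULT_COM_GATE, DEFAULT_EDGE_THRESHOLD, TrackingGraph,
                    build_graph)
from .mask_io import LabeledFrame, MaskMovie

__all__ = ["ScoreMatrix", "AssignmentResult", "solve_budding",
           "solve_fission", "scores_to_matrix", "track_movie"]

DEFAULT_MIN_SCORE = 0.5


@dataclasses.dataclass
class ScoreMatrix:
    matrix: np.ndarray              # (n1, n2) in [0, 1]
    labels_t: list[int]
    labels_t1: list[int]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.labels_t), len(self.labels_t1)):
            raise ValueError("score matrix shape does not match label lists")


@dataclasses.dataclass
class AssignmentResult:
    matches: dict[int, int]         # frame-t label -> frame-t+1 label
    new_cells: list[int]            # frame-t+1 labels with no match
    lost_cells: list[int]           # frame-t labels with no match
    total_score: float


def scores_to_matrix(graph: TrackingGraph, node_scores: np.ndarray,
                     floor: float = 0.0) -> ScoreMatrix:
    """Reshape per-node correct-class scores into the n1 x n2 matrix;
    node pairs pruned from the graph receive the floor value."""
    n1, n2 = len(graph.labels_t), len(graph.labels_t1)
    row = {lab: i for i, lab in enumerate(graph.labels_t)}
    col = {lab: j for j, lab in enumerate(graph.labels_t1)}
    mat = np.full((n1, n2), floor)
    for (a, b), s in zip(graph.nodes, np.asarray(node_scores)[:, 1]):
        mat[row[a], col[b]] = s
    return ScoreMatrix(mat, graph.labels_t, graph.labels_t1)


def solve_budding(scores: ScoreMatrix,
                  min_score: float = DEFAULT_MIN_SCORE) -> AssignmentResult:
    """Maximize total matched score over injective partial matchings of
    size min(n1, n2) (Jonker-Volgenant), then sever matches whose score
    falls below ``min_score`` — genuinely new cells in dense regions must
    not be force-matched."""
    m = scores.matrix
    n1, n2 = m.shape
    if n1 == 0 or n2 == 0:
        return AssignmentResult({}, list(scores.labels_t1),
                                list(scores.labels_t), 0.0)
    rows, cols = optimize.linear_sum_assignment(m, maximize=True)
    matches: dict[int, int] = {}
    total = 0.0
    for i, j in zip(rows, cols):
        if m[i, j] >= min_score:
            matches[scores.labels_t[i]] = scores.labels_t1[j]
            total += float(m[i, j])
    new = [lab for lab in scores.labels_t1 if lab not in matches.values()]
    lost = [lab for lab in scores.labels_t if lab not in matches]
    return AssignmentResult(matches, new, lost, total)


def solve_fission(scores: ScoreMatrix,
                  min_score: float = 0.0) -> AssignmentResult:
    """Budding solve when m >= n; otherwise a binary linear program
    maximizing total score subject to row sums <= 1, column sums <= 1 and
    total matches <= max(2m - n, 0)."""
    mat = scores.matrix
    m, n = mat.shape
    if m >= n:
        return solve_budding(scores, min_score=min_score)
    cap = max(2 * m - n, 0)
    if cap == 0 or m == 0:
        return AssignmentResult({}, list(scores.labels_t1),
                                list(scores.labels_t), 0.0)
    # binary variable per (i, j) pair
    c = -mat.ravel()                                # HiGHS minimizes
    n_var = m * n
    # row sums <= 1, column sums <= 1, total matches <= cap
    A = np.zeros((m + n + 1, n_var))
    for i in range(m):
        A[i, i * n:(i + 1) * n] = 1.0
    for j in range(n):
        A[m + j, j::n] = 1.0
    A[m + n, :] = 1.0
    ub = np.concatenate([np.ones(m + n), [cap]])
    res = optimize.milp(
        c,
        constraints=optimize.LinearConstraint(A, -np.inf, ub),
        integrality=np.ones(n_var),
        bounds=optimize.Bounds(0, 1))
    if not res.success:
        raise RuntimeError(f"fission assignment MILP failed: {res.message}")
    x = np.round(res.x).reshape(m, n).astype(bool)
    matches: dict[int, int] = {}
    total = 0.0
    for i in range(m):
        for j in range(n):
            if x[i, j] and mat[i, j] >= min_score:
                matches[scores.labels_t[i]] = scores.labels_t1[j]
                total += float(mat[i, j])
    new = [lab for lab in scores.labels_t1 if lab not in matches.values()]
    lost = [lab for lab in scores.labels_t if lab not in matches]
    return AssignmentResult(matches, new, lost, total)


def brute_force_budding(matrix: np.ndarray) -> float:
    """Exhaustive-permutation optimum of the balanced/unbalanced linear
    assignment (test oracle; exponential)."""
    m, n = matrix.shape
    if m == 0 or n == 0:
        return 0.0
    best = -np.inf
    if m <= n:
        for perm in itertools.permutations(range(n), m):
            best = max(best, sum(matrix[i, j] for i, j in enumerate(perm)))
    else:
        for perm in itertools.permutations(range(m), n):
            best = max(best, sum(matrix[i, j] for j, i in enumerate(perm)))
    return float(best)


def brute_force_fission(matrix: np.ndarray) -> float:
    """Exhaustive optimum over matchings of size <= max(2m - n, 0)
    (test oracle; exponential)."""
    m, n = matrix.shape
    cap = max(2 * m - n, 0)
    best = 0.0
    for k in range(1, cap + 1):
        for rows in itertools.combinations(range(m), k):
            for cols in itertools.permutations(range(n), k):
                best = max(best, sum(matrix[i, j]
                                     for i, j in zip(rows, cols)))
    return float(best)


# ---------------------------------------------------------------------------
# whole-movie tracking
# ---------------------------------------------------------------------------

def track_movie(movie: MaskMovie, model, mode: str = "budding",
                min_score: float = DEFAULT_MIN_SCORE,
                threshold: float = DEFAULT_EDGE_THRESHOLD,
                com_gate: float | None = DEFAULT_COM_GATE,
                normalize: bool = True,
                ) -> tuple[MaskMovie, pd.DataFrame]:
    """Track a movie with a trained model: frame-0 labels are kept, each
    later frame is relabeled so matched cells inherit the previous frame's
    label and new cells get fresh, never-reused labels.

    Features are computed on an area-normalized copy of the movie (the
    same normalization used at training time); the returned movie carries
    the relabeling applied to the *original* masks, so footprints are
    unchanged. Returns the relabeled movie and an event log with columns
    ``frame,event,label,partner`` (event in {new, lost, division};
    for fission divisions, two rows record the daughters with the retired
    parent label as ``partner``).
    """
    if mode not in ("budding", "fission"):
        raise ValueError(f"unknown mode {mode!r}")
    from .mask_io import normalize_scale
    work = normalize_scale(movie) if normalize else movie
    out_frames = [LabeledFrame(0, movie[0].labels.copy())]
    events: list[tuple[int, str, int, int]] = []
    next_label = int(max((f.labels.max() for f in movie.frames), default=0)) + 1
    prev_geo = FrameGeometry(work[0])
    for t in range(1, len(movie)):
        cur_geo = FrameGeometry(work[t])
        if len(prev_geo) == 0 or len(cur_geo) == 0:
            result = AssignmentResult({}, cur_geo.labels_sorted,
                                      prev_geo.labels_sorted, 0.0)
        else:
            g = build_graph(prev_geo, cur_geo, threshold=threshold,
                            com_gate=com_gate)
            if g.n_nodes == 0:
                result = AssignmentResult({}, cur_geo.labels_sorted,
                                          prev_geo.labels_sorted, 0.0)
            else:
                scores = scores_to_matrix(g, model.forward(g))
                if mode == "fission":
                    result = solve_fission(scores, min_score=0.0)
                else:
                    result = solve_budding(scores, min_score=min_score)
        relabel: dict[int, int] = {}
        for a, b in result.matches.items():
            relabel[b] = a
        for b in result.new_cells:
            relabel[b] = next_label
            next_label += 1
        new_labels = _apply_relabel(movie[t].labels, relabel)
        out_frames.append(LabeledFrame(t, new_labels))
        for b in result.new_cells:
            events.append((t, "new", relabel[b], 0))
        for a in result.lost_cells:
            events.append((t, "lost", a, 0))
        if mode == "fission":
            events.extend(_pair_divisions(t, result, relabel, prev_geo,
                                          work[t].labels))
        prev_geo = cur_geo.relabeled(
            relabel, _apply_relabel(work[t].labels, relabel))
    log = pd.DataFrame(events, columns=["frame", "event", "label", "partner"])
    tracked = MaskMovie(out_frames, movie.frame_interval_minutes,
                        movie.scale_factor)
    return tracked, log


def _apply_relabel(labels: np.ndarray, mapping: dict[int, int]) -> np.ndarray:
    out = np.zeros_like(labels)
    for old, new in mapping.items():
        out[labels == old] = new
    return out


def _pair_divisions(t: int, result: AssignmentResult,
                    relabel: dict[int, int], prev_geo: FrameGeometry,
                    raw_labels: np.ndarray) -> list[tuple[int, str, int, int]]:
    """Attribute simultaneous new cells to vanished parents: each pair of
    new cells overlapping a lost cell's last footprint is a division; the
    daughter-parent pairing maximizes mask overlap, ties broken by closest
    CoM."""
    events = []
    if not result.lost_cells or len(result.new_cells) < 2:
        return events
    prev_labels = prev_geo.frame.labels
    overlap: dict[int, list[tuple[float, float, int]]] = {}
    for lost in result.lost_cells:
        lost_mask = prev_labels == lost
        lost_com = prev_geo.record(lost).com
        cands = []
        for b in result.new_cells:
            new_mask = raw_labels == b
            ov = int(np.count_nonzero(lost_mask & new_mask))
            coords = np.argwhere(new_mask)
            com = coords.mean(axis=0)
            d = float(np.hypot(com[0] - lost_com[0], com[1] - lost_com[1]))
            cands.append((-ov, d, b))
        cands.sort()
        overlap[lost] = cands
    claimed: set[int] = set()
    for lost, cands in overlap.items():
        daughters = [b for ov, d, b in cands
                     if -ov > 0 and b not in claimed][:2]
        if len(daughters) == 2:
            claimed.update(daughters)
            for b in daughters:
                events.append((t, "division", relabel[b], lost))
    return events
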