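"""Lineage tracing: assigning a mother cell to each new bud.

Three methods are provided, mirroring decreasing information content:

* **fluorescence vote** (`trace_fluo`): when a bud-neck marker channel is
  available, blur each of the first frames after budding, find the
  brightest point along the bud's contour and vote for the nearest cell —
  near-perfect when the marker is present;
* **geometric classifier** (`trace_nn_*`): a small fully connected
  network scores each (bud, candidate-mother) pair from 15 dynamic
  geometric features computed over the N = 8 frames following budding —
  capturing the biological biases in where buds appear, how they grow and
  how they are oriented relative to their mothers;
* **nearest-cell baseline** (`nearest_cell_baseline`): the classical
  approach; fails frequently for buds in colony interiors.

The feature set and the greedy backward elimination protocol used to
prune it are implemented generically over a named feature schema.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .features import FrameGeometry
from .mask_io import LineageTable, MaskMovie

__all__ = [
    "LINEAGE_FEATURE_NAMES", "BudCase", "TraceNNConfig", "TraceNN",
    "select_candidates", "extract_lineage_features", "collect_bud_cases",
    "trace_nn_train", "trace_nn_predict", "trace_fluo",
    "nearest_cell_baseline", "backward_eliminate", "trace_movie",
]

DEFAULT_N_FRAMES = 8
DEFAULT_MAX_CANDIDATES = 4
DEFAULT_MAX_DIST = 12.0

LINEAGE_FEATURE_NAMES = [
    "contour_dist_at_budding",
    "contour_dist_std",
    "contour_dist_min",
    "contour_dist_max",
    "contour_dist_range",
    "com_recede_speed",
    "farpoint_recede_speed",
    "orient_at_N",
    "orient_change_N",
    "orient_min",
    "orient_speed",
    "posangle_change_N",
    "posangle_std",
    "posangle_min",
    "posangle_max",
]


class InsufficientHistoryError(ValueError):
    pass


@dataclasses.dataclass
class BudCase:
    bud_id: int
    budding_frame: int
    candidates: list[tuple[int, np.ndarray]]   # (mother candidate, features)
    true_mother: int | None = None
    n_frames_used: int = 0
    candidate_distances: list[float] = dataclasses.field(default_factory=list)


def select_candidates(bud_id: int, geo: FrameGeometry,
                      max_candidates: int = DEFAULT_MAX_CANDIDATES,
                      max_dist: float = DEFAULT_MAX_DIST,
                      ) -> list[tuple[int, float]]:
    """Candidate mothers: cells within ``max_dist`` contour-to-contour
    distance of the bud, sorted ascending by that distance (label breaks
    ties), truncated to the closest ``max_candidates``."""
    cands = []
    for other in geo.neighbors_within(bud_id, max_dist):
        cands.append((geo.closest_distance(bud_id, other), other))
    cands.sort()
    return [(lab, d) for d, lab in cands[:max_candidates]]


def _axis_angle_to_line(axis_theta: float, line_vec: np.ndarray) -> float:
    """Acute angle in [0, pi/2] between an undirected axis (world angle to
    the column axis) and a directed line."""
    norm = float(np.hypot(*line_vec))
    if norm < 1e-9:
        return 0.0
    u = np.array([np.sin(axis_theta), np.cos(axis_theta)])   # (row, col)
    cosang = abs(float(u @ line_vec) / norm)
    return float(np.arccos(np.clip(cosang, 0.0, 1.0)))


def extract_lineage_features(bud_id: int, candidate_id: int,
                             geos: "list[FrameGeometry] | _GeoSeries",
                             budding_frame: int,
                             n_frames: int = DEFAULT_N_FRAMES,
                             ) -> tuple[np.ndarray, int]:
    """The 15 dynamic features of one (bud, candidate-mother) pair.

    Per frame of the window [budding_frame, budding_frame + n_frames):
    contour-to-contour distance; distance from the bud CoM to the
    candidate's contour; distance from the bud's farthest point (from the
    candidate) to the candidate's contour; the *orientation* angle between
    the bud's major axis and the line from the candidate's CoM to the
    point of its contour closest to the bud; and the *position angle*
    between the candidate's major axis and that same line. Angles are
    unsigned, in [0, pi/2]. "Speeds" are slopes of linear regressions
    over the window. Returns (features, n_frames_actually_used); fewer
    frames than requested is allowed (movie end or track loss) down to a
    floor of 2.
    """
    ds, com_ds, far_ds, orients, posangles = [], [], [], [], []
    for t in range(budding_frame, budding_frame + n_frames):
        geo = geos[t] if t < len(geos) else None
        if geo is None or bud_id not in geo.records \
                or candidate_id not in geo.records:
            break
        bud = geo.record(bud_id)
        cand = geo.record(candidate_id)
        ds.append(geo.closest_distance(bud_id, candidate_id))
        ctree = geo.tree(candidate_id)
        # bud CoM -> candidate contour
        d_com, _ = ctree.query(np.asarray(bud.com))
        com_ds.append(float(d_com))
        # bud's farthest point from the candidate -> candidate contour
        dists_bud, _ = ctree.query(bud.contour)
        far_ds.append(float(np.max(dists_bud)))
        # closest point of the candidate contour to the bud
        btree = geo.tree(bud_id)
        d_to_bud, _ = btree.query(cand.contour)
        p = cand.contour[int(np.argmin(d_to_bud))]
        line = p - np.asarray(cand.com)
        orients.append(_axis_angle_to_line(bud.features.orientation, line))
        posangles.append(_axis_angle_to_line(cand.features.orientation, line))
    n = len(ds)
    if n < 2:
        raise InsufficientHistoryError(
            f"bud {bud_id} and candidate {candidate_id} share only {n} "
            f"frame(s) after budding")
    tvec = np.arange(n, dtype=float)

    def slope(series):
        return float(np.polyfit(tvec, np.asarray(series), 1)[0])

    ds = np.asarray(ds)
    orients_a = np.asarray(orients)
    pos_a = np.asarray(posangles)
    feats = np.array([
        ds[0],
        float(ds.std()),
        float(ds.min()),
        float(ds.max()),
        float(ds.max() - ds.min()),
        slope(com_ds),
        slope(far_ds),
        float(orients_a[-1]),
        float(orients_a[-1] - orients_a[0]),
        float(orients_a.min()),
        slope(orients_a),
        float(pos_a[-1] - pos_a[0]),
        float(pos_a.std()),
        float(pos_a.min()),
        float(pos_a.max()),
    ])
    return feats, n


class _GeoSeries:
    """Lazily built, cached FrameGeometry per frame of a movie."""

    def __init__(self, movie: MaskMovie):
        self.movie = movie
        self._cache: dict[int, FrameGeometry] = {}

    def __len__(self) -> int:
        return len(self.movie)

    def __getitem__(self, i: int) -> FrameGeometry:
        if i not in self._cache:
            self._cache[i] = FrameGeometry(self.movie[i])
        return self._cache[i]


def collect_bud_cases(movie: MaskMovie,
                      buds: list[tuple[int, int]],
                      lineage: LineageTable | None = None,
                      n_frames: int = DEFAULT_N_FRAMES,
                      max_candidates: int = DEFAULT_MAX_CANDIDATES,
                      max_dist: float = DEFAULT_MAX_DIST,
                      geos: _GeoSeries | None = None,
                      ) -> list[BudCase]:
    """Build :class:`BudCase` records for (bud_id, budding_frame) pairs on
    a tracked movie. Buds with zero candidates or insufficient history are
    skipped (they are unassignable)."""
    geos = geos or _GeoSeries(movie)
    truth = ({int(r.bud_id): int(r.mother_id) for r in lineage}
             if lineage is not None else {})
    cases = []
    for bud_id, frame in buds:
        geo = geos[frame]
        if bud_id not in geo.records:
            continue
        cand_ids = select_candidates(bud_id, geo, max_candidates, max_dist)
        feats, dists, n_used = [], [], 0
        for cid, d in cand_ids:
            try:
                f, n_used = extract_lineage_features(
                    bud_id, cid, geos, frame, n_frames)
            except InsufficientHistoryError:
                continue
            feats.append((cid, f))
            dists.append(d)
        if not feats:
            continue
        cases.append(BudCase(bud_id=bud_id, budding_frame=frame,
                             candidates=feats,
                             true_mother=truth.get(bud_id),
                             n_frames_used=n_used,
                             candidate_distances=dists))
    return cases


# ---------------------------------------------------------------------------
# fully connected classifier
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TraceNNConfig:
    hidden_layers: int = 2      # the evaluated model has two; three available
    hidden_dim: int = 32
    dropout: float = 0.2
    epochs: int = 150
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.hidden_layers not in (1, 2, 3):
            raise ValueError("hidden_layers must be 1, 2 or 3")


class TraceNN:
    """Per-candidate binary classifier: mother vs non-mother.

    Hidden layers apply affine -> batch normalization -> ELU -> dropout;
    the output layer is a 2-class softmax. Each candidate is scored
    independently, so variable candidate counts are handled naturally;
    the predicted mother is the argmax of the mother-class confidence.
    Feature z-scoring statistics are frozen at training time.

    Forward and backward passes are hand-derived plain numpy: the network
    is tiny (tens of units) and is retrained thousands of times during
    feature elimination, so per-call overhead matters far more than
    generality here.
    """

    def __init__(self, config: TraceNNConfig, n_features: int,
                 feature_names: list[str] | None = None):
        self.config = config
        self.n_features = n_features
        self.feature_names = feature_names or list(LINEAGE_FEATURE_NAMES)
        self.mean = np.zeros(n_features)
        self.std = np.ones(n_features)
        rng = np.random.default_rng(config.seed)
        dims = [n_features] + [config.hidden_dim] * config.hidden_layers
        p: dict[str, np.ndarray] = {}
        for i in range(config.hidden_layers):
            p[f"W{i}"] = rng.normal(0.0, np.sqrt(2.0 / dims[i]),
                                    (dims[i], dims[i + 1]))
            p[f"b{i}"] = np.zeros(dims[i + 1])
            p[f"bn{i}_g"] = np.ones(dims[i + 1])
            p[f"bn{i}_b"] = np.zeros(dims[i + 1])
        p["Wout"] = rng.normal(0.0, np.sqrt(2.0 / dims[-1]), (dims[-1], 2))
        p["bout"] = np.zeros(2)
        self.params = p
        self.bn_running = [(np.zeros(config.hidden_dim),
                            np.ones(config.hidden_dim))
                           for _ in range(config.hidden_layers)]

    def _forward(self, X: np.ndarray, train: bool = False,
                 rng: np.random.Generator | None = None):
        """Logits plus (in training mode) the per-layer caches needed for
        the analytic backward pass."""
        cfg = self.config
        p = self.params
        h = (X - self.mean) / self.std
        caches = []
        for i in range(cfg.hidden_layers):
            z = h @ p[f"W{i}"] + p[f"b{i}"]
            if train:
                mu = z.mean(axis=0)
                c = z - mu
                var = (c * c).mean(axis=0)
                inv = 1.0 / np.sqrt(var + 1e-5)
                zn = c * inv
                rm, rv = self.bn_running[i]
                self.bn_running[i] = (0.9 * rm + 0.1 * mu, 0.9 * rv + 0.1 * var)
            else:
                rm, rv = self.bn_running[i]
                inv = 1.0 / np.sqrt(rv + 1e-5)
                c = z - rm
                zn = c * inv
            a = zn * p[f"bn{i}_g"] + p[f"bn{i}_b"]
            pos = a > 0
            e = np.where(pos, a, np.exp(np.minimum(a, 0.0)) - 1.0)
            if train and cfg.dropout > 0:
                mask = (rng.random(e.shape) >= cfg.dropout) / (1 - cfg.dropout)
                out = e * mask
            else:
                mask = None
                out = e
            caches.append((h, c, inv, zn, pos, e, mask))
            h = out
        logits = h @ p["Wout"] + p["bout"]
        return logits, h, caches

    def _backward(self, dlogits: np.ndarray, h_last: np.ndarray,
                  caches: list) -> dict[str, np.ndarray]:
        cfg = self.config
        p = self.params
        g: dict[str, np.ndarray] = {}
        g["Wout"] = h_last.T @ dlogits
        g["bout"] = dlogits.sum(axis=0)
        dh = dlogits @ p["Wout"].T
        for i in reversed(range(cfg.hidden_layers)):
            hin, c, inv, zn, pos, e, mask = caches[i]
            if mask is not None:
                dh = dh * mask
            da = dh * np.where(pos, 1.0, e + 1.0)        # ELU' (alpha = 1)
            g[f"bn{i}_g"] = (da * zn).sum(axis=0)
            g[f"bn{i}_b"] = da.sum(axis=0)
            dzn = da * p[f"bn{i}_g"]
            n = dzn.shape[0]
            # batch-norm backward (through batch statistics)
            dz = (inv / n) * (n * dzn - dzn.sum(axis=0)
                              - zn * (dzn * zn).sum(axis=0))
            g[f"W{i}"] = hin.T @ dz
            g[f"b{i}"] = dz.sum(axis=0)
            dh = dz @ p[f"W{i}"].T
        return g

    def logits(self, X: np.ndarray) -> np.ndarray:
        return self._forward(X, train=False)[0]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = self.logits(X)
        z = z - z.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True)

    def state(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()} | {
            f"_rn{i}": np.concatenate(self.bn_running[i])
            for i in range(self.config.hidden_layers)}

    def set_state(self, state: dict) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()
        for i in range(self.config.hidden_layers):
            rn = state[f"_rn{i}"]
            half = len(rn) // 2
            self.bn_running[i] = (rn[:half].copy(), rn[half:].copy())


def _cases_to_arrays(cases: list[BudCase],
                     feature_idx: np.ndarray | None = None):
    X, y, case_of = [], [], []
    for ci, case in enumerate(cases):
        for cid, f in case.candidates:
            X.append(f if feature_idx is None else f[feature_idx])
            y.append(1 if cid == case.true_mother else 0)
            case_of.append(ci)
    return np.array(X), np.array(y), np.array(case_of)


def trace_nn_train(cases: list[BudCase], config: TraceNNConfig,
                   feature_idx: np.ndarray | None = None,
                   val_cases: list[BudCase] | None = None,
                   ) -> tuple[TraceNN, dict]:
    """Train the mother classifier on labeled bud cases.

    Positives are the true-mother candidates. If ``val_cases`` is given,
    the returned parameters are those of the epoch with the lowest
    validation loss. Identical seeds give identical parameters.
    """
    X, y, _ = _cases_to_arrays(cases, feature_idx)
    Xv = yv = None
    if val_cases:
        Xv, yv, _ = _cases_to_arrays(val_cases, feature_idx)
    return _fit_arrays(X, y, config, feature_idx, Xv, yv)


def _fit_arrays(X: np.ndarray, y: np.ndarray, config: TraceNNConfig,
                feature_idx: np.ndarray | None = None,
                Xv: np.ndarray | None = None,
                yv: np.ndarray | None = None) -> tuple[TraceNN, dict]:
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate training set: single class")
    n_feats = X.shape[1]
    names = (list(LINEAGE_FEATURE_NAMES)
             if feature_idx is None and n_feats == len(LINEAGE_FEATURE_NAMES)
             else None)
    model = TraceNN(config, n_feats, names)
    model.mean = X.mean(axis=0)
    model.std = np.maximum(X.std(axis=0), 1e-6)
    rng = np.random.default_rng(config.seed + 1)
    onehot = np.zeros((len(y), 2))
    onehot[np.arange(len(y)), y] = 1.0
    # Adam state over the plain-numpy parameter dict
    mom = {k: np.zeros_like(v) for k, v in model.params.items()}
    vel = {k: np.zeros_like(v) for k, v in model.params.items()}
    b1, b2, eps, lr = 0.9, 0.999, 1e-8, config.learning_rate
    losses, val_losses = [], []
    best = (np.inf, None)
    for epoch in range(config.epochs):
        z, h_last, caches = model._forward(X, train=True, rng=rng)
        zs = z - z.max(axis=1, keepdims=True)
        ez = np.exp(zs)
        prob = ez / ez.sum(axis=1, keepdims=True)
        losses.append(float(-np.log(np.maximum(
            prob[np.arange(len(y)), y], 1e-12)).mean()))
        grads = model._backward((prob - onehot) / len(y), h_last, caches)
        t = epoch + 1
        for k, gk in grads.items():
            mom[k] = b1 * mom[k] + (1 - b1) * gk
            vel[k] = b2 * vel[k] + (1 - b2) * gk * gk
            model.params[k] -= lr * (mom[k] / (1 - b1 ** t)) \
                / (np.sqrt(vel[k] / (1 - b2 ** t)) + eps)
        if Xv is not None:
            p = model.predict_proba(Xv)
            vl = float(-np.log(np.maximum(p[np.arange(len(yv)), yv],
                                          1e-12)).mean())
            val_losses.append(vl)
            if vl < best[0]:
                best = (vl, model.state())
    if best[1] is not None:
        model.set_state(best[1])
    metrics = {"train_loss": losses, "val_loss": val_losses}
    return model, metrics


def trace_nn_predict(case: BudCase, model: TraceNN,
                     feature_idx: np.ndarray | None = None,
                     ) -> tuple[int, dict[int, float]]:
    """Predicted mother id and per-candidate mother-class confidences.

    Candidates are scored independently; the argmax wins. Candidates are
    ordered by contour distance, so exact ties resolve to the closest.
    """
    X = np.array([f if feature_idx is None else f[feature_idx]
                  for _, f in case.candidates])
    probs = model.predict_proba(X)[:, 1]
    order = int(np.argmax(probs))
    conf = {cid: float(p) for (cid, _), p in zip(case.candidates, probs)}
    return case.candidates[order][0], conf


# ---------------------------------------------------------------------------
# fluorescence-based tracing and the nearest-cell baseline
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FluoTraceResult:
    mother_id: int | None
    votes: dict[int, int]
    low_confidence: bool


def trace_fluo(bud_id: int, budding_frame: int, movie: MaskMovie,
               fluo: np.ndarray, sigma: float = 1.0,
               n_frames: int = DEFAULT_N_FRAMES, gate: float = 20.0,
               margin: float = 0.1,
               geos: _GeoSeries | None = None) -> FluoTraceResult:
    """Bud-neck-marker mother assignment by majority vote.

    For each of the first ``n_frames`` frames after budding: blur the
    fluorescence image (Gaussian, std ``sigma``), take the bud-contour
    pixel with the highest blurred intensity, and vote for the cell
    (other than the bud) whose contour is nearest to that peak; frames
    where no other cell lies within ``gate`` px of the peak abstain.
    Ties go to the candidate seen in the earliest frame; the result is
    flagged low-confidence when the winning vote share is below
    0.5 + ``margin``.
    """
    if fluo.shape[0] != len(movie):
        raise ValueError("fluorescence stack and movie differ in length")
    geos = geos or _GeoSeries(movie)
    votes: dict[int, int] = {}
    first_seen: dict[int, int] = {}
    for k, t in enumerate(range(budding_frame,
                                min(budding_frame + n_frames, len(movie)))):
        geo = geos[t]
        if bud_id not in geo.records:
            break
        blurred = ndimage.gaussian_filter(fluo[t].astype(float), sigma)
        contour = geo.record(bud_id).contour
        rr = np.clip(np.round(contour[:, 0]).astype(int), 0,
                     blurred.shape[0] - 1)
        cc = np.clip(np.round(contour[:, 1]).astype(int), 0,
                     blurred.shape[1] - 1)
        peak = np.array([rr[np.argmax(blurred[rr, cc])],
                         cc[np.argmax(blurred[rr, cc])]], dtype=float)
        best: tuple[float, int] | None = None
        for other in geo.labels_sorted:
            if other == bud_id:
                continue
            d, _ = geo.tree(other).query(peak)
            if best is None or d < best[0]:
                best = (float(d), other)
        if best is None or best[0] > gate:
            continue
        votes[best[1]] = votes.get(best[1], 0) + 1
        first_seen.setdefault(best[1], k)
    if not votes:
        return FluoTraceResult(None, votes, True)
    top = max(votes.values())
    winners = [c for c, v in votes.items() if v == top]
    mother = min(winners, key=lambda c: first_seen[c])
    share = top / sum(votes.values())
    return FluoTraceResult(mother, votes, share < 0.5 + margin)


def nearest_cell_baseline(bud_id: int, geo: FrameGeometry) -> int | None:
    """The cell with minimal closest contour distance to the bud
    (ties -> lowest label); None if the bud is the only cell."""
    best: tuple[float, int] | None = None
    for other in geo.labels_sorted:
        if other == bud_id:
            continue
        d = geo.closest_distance(bud_id, other)
        if best is None or (d, other) < best:
            best = (d, other)
    return best[1] if best else None


# ---------------------------------------------------------------------------
# end-to-end tracing of a tracked movie
# ---------------------------------------------------------------------------

def trace_movie(movie: MaskMovie, model: TraceNN,
                buds: list[tuple[int, int]] | None = None,
                n_frames: int = DEFAULT_N_FRAMES) -> LineageTable:
    """Predict a lineage table for a tracked movie. ``buds`` defaults to
    every label that first appears after frame 0."""
    if buds is None:
        buds = new_cell_events(movie)
    geos = _GeoSeries(movie)
    cases = collect_bud_cases(movie, buds, n_frames=n_frames, geos=geos)
    rows = []
    for case in cases:
        mother, _ = trace_nn_predict(case, model)
        rows.append((case.bud_id, mother, case.budding_frame))
    return LineageTable(rows)


def new_cell_events(movie: MaskMovie) -> list[tuple[int, int]]:
    """(label, frame) for every label first appearing after frame 0."""
    seen = set(movie[0].cell_ids)
    out = []
    for t in range(1, len(movie)):
        for lab in sorted(movie[t].cell_ids - seen):
            out.append((lab, t))
        seen |= movie[t].cell_ids
    return out


# ---------------------------------------------------------------------------
# greedy backward feature elimination
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EliminationResult:
    order_removed: list[str]            # first removed first
    sizes: list[int]                    # feature-set size per step
    cv_mean: list[float]                # mean 5-fold CV accuracy per size
    cv_std: list[float]
    best_size: int
    best_features: list[str]
    test_accuracy_full: float           # held-out test accuracy, full set


class _CVEvaluator:
    """Precomputed fold arrays for repeated subset evaluations.

    Backward elimination retrains the classifier for every candidate
    subset at every step; rebuilding the candidate arrays and predicting
    case by case would dominate the runtime, so the per-fold train/val
    arrays and per-case row slices are built once and column-sliced."""

    def __init__(self, cases: list[BudCase], n_folds: int,
                 fold_of: np.ndarray):
        self.n_folds = n_folds
        X, y, case_of = _cases_to_arrays(cases)
        self.folds = []
        for fold in range(n_folds):
            va_mask = np.array([fold_of[c] == fold for c in case_of])
            Xtr, ytr = X[~va_mask], y[~va_mask]
            Xva, yva = X[va_mask], y[va_mask]
            va_case = case_of[va_mask]
            slices = []          # (start, stop, index-of-true-row or -1)
            start = 0
            for ci in np.unique(va_case):
                rows = np.flatnonzero(va_case == ci)
                stop = start + len(rows)
                true_rows = np.flatnonzero(yva[rows] == 1)
                slices.append((start, stop,
                               int(true_rows[0]) if len(true_rows) else -1))
                start = stop
            self.folds.append((Xtr, ytr, Xva, slices))

    def evaluate(self, idx: np.ndarray, config: TraceNNConfig
                 ) -> tuple[float, float, float]:
        """(mean, std of per-fold assignment accuracy, mean val loss).

        The loss only breaks ties between subsets whose accuracies are
        identical (accuracy is quantized at 1/|fold|)."""
        accs, vls = [], []
        for Xtr, ytr, Xva, slices in self.folds:
            model, _ = _fit_arrays(Xtr[:, idx], ytr, config, idx)
            p = model.predict_proba(Xva[:, idx])[:, 1]
            correct = 0
            vl = []
            for start, stop, true_pos in slices:
                pred = int(np.argmax(p[start:stop]))
                correct += pred == true_pos
                p_true = p[start + true_pos] if true_pos >= 0 else 1e-12
                vl.append(-np.log(max(p_true, 1e-12)))
            accs.append(correct / len(slices) if slices else 0.0)
            vls.append(float(np.mean(vl)) if vl else 0.0)
        return float(np.mean(accs)), float(np.std(accs)), float(np.mean(vls))


def _cv_accuracy(cases: list[BudCase], idx: np.ndarray,
                 config: TraceNNConfig, n_folds: int,
                 fold_of: np.ndarray) -> tuple[float, float, float]:
    return _CVEvaluator(cases, n_folds, fold_of).evaluate(idx, config)


def backward_eliminate(cases: list[BudCase], feature_names: list[str],
                       config: TraceNNConfig, n_folds: int = 5,
                       test_fraction: float = 0.2,
                       min_size: int = 1,
                       seed: int = 0) -> EliminationResult:
    """Greedy backward feature elimination with k-fold cross-validation.

    The data are first split into a training portion and a held-out test
    portion (default 80/20) — the test portion is never consulted for
    selection decisions. At each step, every single-feature-removed
    subset is retrained under ``n_folds``-fold CV on the training portion
    and the feature whose removal yields the highest mean validation
    accuracy is eliminated, from the full set down to ``min_size``
    features. Splits are by budding event. Per-size CV accuracy is the
    direct CV run with the *current* (pre-removal) set.
    """
    if len(feature_names) < 2:
        raise ValueError("need at least 2 features to eliminate")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    n_test = int(round(test_fraction * len(cases)))
    test_cases = [cases[i] for i in order[:n_test]]
    train_cases = [cases[i] for i in order[n_test:]]
    fold_of = np.arange(len(train_cases)) % n_folds
    rng.shuffle(fold_of)

    evaluator = _CVEvaluator(train_cases, n_folds, fold_of)
    current = np.arange(len(feature_names))
    removed: list[str] = []
    sizes, cv_mean, cv_std = [], [], []
    while len(current) >= max(min_size, 1):
        mu, sd, _ = evaluator.evaluate(current, config)
        sizes.append(len(current))
        cv_mean.append(mu)
        cv_std.append(sd)
        if len(current) <= min_size or len(current) == 1:
            break
        best = None
        for k in range(len(current)):
            sub = np.delete(current, k)
            mu_k, _, vl_k = evaluator.evaluate(sub, config)
            # highest mean validation accuracy wins; exact accuracy ties
            # (quantized metric) break toward lower validation loss
            key = (mu_k, -vl_k)
            if best is None or key > best[0]:
                best = (key, k)
        removed.append(feature_names[current[best[1]]])
        current = np.delete(current, best[1])

    best_i = int(np.argmax(cv_mean))
    kept_at = _kept_at_size(feature_names, removed, sizes[best_i])
    # held-out test accuracy with the full feature set
    full_idx = np.arange(len(feature_names))
    model, _ = trace_nn_train(train_cases, config, feature_idx=full_idx)
    test_acc = (sum(trace_nn_predict(c, model, feature_idx=full_idx)[0]
                    == c.true_mother for c in test_cases)
                / len(test_cases)) if test_cases else float("nan")
    return EliminationResult(order_removed=removed, sizes=sizes,
                             cv_mean=cv_mean, cv_std=cv_std,
                             best_size=sizes[best_i], best_features=kept_at,
                             test_accuracy_full=test_acc)


def _kept_at_size(names: list[str], removed: list[str], size: int) -> list[str]:
    drop = set(removed[:len(names) - size])
    return [n for n in names if n not in drop]
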