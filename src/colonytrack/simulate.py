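"""Synthetic growing-colony simulator with exact ground truth.

Generates labeled mask movies that emulate the statistical structure the
tracker and the lineage tracer assume in real recordings: densely packed
touching cells, exponential growth, asymmetric budding (budding yeast) or
symmetric medial fission (rod-shaped fission yeast), and passive
displacement of cells caused by colony expansion. Because every cell's
identity is known by construction, the simulator emits exact tracking
correspondences and a mother->bud lineage table, plus an optional
fluorescence channel with a Gaussian spot rendered at each active
bud-mother junction (emulating a bud-neck marker such as a myosin ring).

Model choices, briefly:

* budding cells are mildly elongated ellipses; fission cells are capsules
  (rectangles with semicircular caps), giving them the distinctive length
  scales that make rod tracking comparatively easy;
* a mother past a stochastic maturity size nucleates a touching bud whose
  placement is biased toward the mother's polar caps (``bud_site_bias`` =
  probability of a polar bud) — this biological bias is exactly what makes
  geometry-based lineage tracing learnable beyond nearest-cell assignment;
* buds keep their own label forever and mothers keep theirs (budding
  convention); at fission both daughters get fresh labels and the parent
  label is retired (fission convention);
* overlaps are resolved by iterative pairwise repulsion, so colony
  expansion and passive cell displacement emerge without a physics engine;
* rasterization assigns contested pixels to the cell whose normalized
  shape function is smallest, so masks are always disjoint and touching.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .mask_io import LabeledFrame, LineageTable, MaskMovie

__all__ = ["ColonyConfig", "SyntheticGroundTruth", "simulate", "subsample",
           "SimulationError"]


class SimulationError(RuntimeError):
    pass


@dataclasses.dataclass
class ColonyConfig:
    mode: str = "budding"               # {"budding", "fission"}
    n_frames: int = 60
    initial_cells: int = 2
    canvas: int = 512
    frame_interval_minutes: float = 5.0
    #: frames per cell cycle; 18 frames at 5-min intervals matches a colony
    #: doubling time of about 90 min in rich medium.
    mean_cell_cycle_frames: float = 18.0
    growth_rate_cv: float = 0.15
    bud_site_bias: float = 0.8          # P(bud placed in a polar cap)
    daughter_initial_fraction: float = 0.18
    mature_area: float = 600.0          # px^2, mean adult cell area
    crowding_push_strength: float = 1.0
    fluo: str = "none"                  # {"none", "junction_spot"}
    spot_intensity: float = 3000.0
    spot_sigma: float = 2.0
    spot_frames: int = 8                # frames a junction spot stays lit
    fission_width: float = 9.0          # px, rod width
    #: freeze all dynamics (no growth, drift or division): every frame is
    #: identical. Useful for testing stationary-geometry code paths.
    frozen: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("budding", "fission"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.5 <= self.bud_site_bias <= 1.0):
            raise ValueError("bud_site_bias must be in [0.5, 1]")
        if self.n_frames < 1 or self.initial_cells < 1:
            raise ValueError("need >= 1 frame and >= 1 initial cell")
        for name in ("mean_cell_cycle_frames", "mature_area",
                     "daughter_initial_fraction", "canvas"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclasses.dataclass
class SyntheticGroundTruth:
    movie: MaskMovie
    lineage: LineageTable
    tracklets: list[dict[int, int]]     # per transition: label_t -> label_t1
    fluorescence: np.ndarray | None = None
    config: ColonyConfig | None = None


# ---------------------------------------------------------------------------
# cell state
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class _Cell:
    label: int
    center: np.ndarray                  # (row, col) float
    area: float
    theta: float                        # axial orientation, radians
    aspect: float                       # major/minor semi-axis ratio (>= 1)
    mature_area: float
    cycle: float                        # frames between budding events
    countdown: float                    # frames until next division event
    mother: int = 0
    birth_frame: int = -1
    attached_to: int | None = None      # mother label while bud is attached
    length: float = 0.0                 # fission rods only
    width: float = 0.0

    def semiaxes(self) -> tuple[float, float]:
        b = np.sqrt(self.area / (np.pi * self.aspect))
        return self.aspect * b, b

    def radius(self) -> float:
        return float(np.sqrt(self.area / np.pi))

    def boundary_radius(self, phi: float) -> float:
        """Ellipse radius in direction phi (from center, world angle)."""
        a, b = self.semiaxes()
        psi = phi - self.theta
        return a * b / np.hypot(b * np.cos(psi), a * np.sin(psi))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate(config: ColonyConfig) -> SyntheticGroundTruth:
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.mode == "budding":
        return _simulate_budding(config, rng)
    return _simulate_fission(config, rng)


def _draw_cycle(cfg: ColonyConfig, rng) -> float:
    mu = cfg.mean_cell_cycle_frames
    return float(max(4.0, rng.normal(mu, cfg.growth_rate_cv * mu)))


def _simulate_budding(cfg: ColonyConfig, rng) -> SyntheticGroundTruth:
    cells: list[_Cell] = []
    c0 = cfg.canvas / 2.0
    next_label = 1
    for _ in range(cfg.initial_cells):
        pos = np.array([c0, c0]) + rng.normal(0, 6.0 * cfg.initial_cells, 2)
        cells.append(_Cell(
            label=next_label, center=pos,
            area=float(rng.uniform(0.8, 1.0) * cfg.mature_area),
            theta=float(rng.uniform(-np.pi / 2, np.pi / 2)),
            aspect=float(rng.uniform(1.05, 1.3)),
            mature_area=float(rng.normal(cfg.mature_area,
                                         0.08 * cfg.mature_area)),
            cycle=_draw_cycle(cfg, rng),
            countdown=float(rng.uniform(1, cfg.mean_cell_cycle_frames)),
            birth_frame=0))
        next_label += 1

    frames, lineage_rows, tracklets = [], [], []
    fluo_frames = [] if cfg.fluo == "junction_spot" else None
    junctions: dict[int, tuple[int, int]] = {}   # bud label -> (mother, birth)

    for t in range(cfg.n_frames):
        if t > 0 and not cfg.frozen:
            # growth: buds grow toward maturity, adults creep slowly
            for c in cells:
                if c.area < c.mature_area:
                    g = (1.0 / cfg.daughter_initial_fraction) ** (1.0 / c.cycle)
                    c.area *= g * float(np.exp(rng.normal(0, 0.02)))
                    c.area = min(c.area, c.mature_area * 1.05)
                else:
                    c.area *= float(np.exp(rng.normal(0.002, 0.005)))
                c.theta = _fold(c.theta + rng.normal(0, 0.02))
                if c.attached_to is not None and c.area > 0.6 * c.mature_area:
                    c.attached_to = None     # bud detaches once sizeable
                c.countdown -= 1.0

            # budding: mature cells past their countdown nucleate a bud
            for c in list(cells):
                if c.area >= 0.9 * c.mature_area and c.countdown <= 0:
                    bud = _nucleate_bud(cfg, rng, c, next_label, t)
                    cells.append(bud)
                    lineage_rows.append((bud.label, c.label, t))
                    junctions[bud.label] = (c.label, t)
                    next_label += 1
                    c.countdown = c.cycle
        if not (cfg.frozen and t > 0):
            _relax_budding(cfg, cells)
            _recenter(cfg, cells)

        labels_img = _rasterize_ellipses(cfg, cells)
        frames.append(LabeledFrame(index=t, labels=labels_img))
        if t > 0:
            prev = frames[-2].cell_ids
            cur = frames[-1].cell_ids
            tracklets.append({lab: lab for lab in prev & cur})
        if fluo_frames is not None:
            fluo_frames.append(_render_fluo(cfg, rng, cells, junctions, t))

    movie = MaskMovie(frames, frame_interval_minutes=cfg.frame_interval_minutes)
    return SyntheticGroundTruth(
        movie=movie, lineage=LineageTable(lineage_rows), tracklets=tracklets,
        fluorescence=(np.stack(fluo_frames) if fluo_frames else None),
        config=cfg)


def _nucleate_bud(cfg: ColonyConfig, rng, mother: _Cell,
                  label: int, t: int) -> _Cell:
    # polar placement with probability bud_site_bias, else uniform
    if rng.random() < cfg.bud_site_bias:
        pole = mother.theta + (0.0 if rng.random() < 0.5 else np.pi)
        phi = pole + rng.normal(0, np.deg2rad(15))
    else:
        phi = rng.uniform(-np.pi, np.pi)
    area = cfg.daughter_initial_fraction * mother.area
    r_bud = np.sqrt(area / np.pi)
    dist = mother.boundary_radius(phi) + r_bud - 1.5   # slight overlap: touch
    center = mother.center + dist * np.array([np.sin(phi), np.cos(phi)])
    return _Cell(
        label=label, center=center, area=float(area),
        theta=_fold(phi + rng.normal(0, 0.15)),        # bud points radially
        aspect=float(rng.uniform(1.05, 1.25)),
        mature_area=float(rng.normal(cfg.mature_area, 0.08 * cfg.mature_area)),
        cycle=_draw_cycle(cfg, rng) * 1.2,             # daughters cycle slower
        countdown=_draw_cycle(cfg, rng),
        mother=mother.label, birth_frame=t, attached_to=mother.label)


def _relax_budding(cfg: ColonyConfig, cells: list[_Cell],
                   max_iter: int = 400, max_step: float = 1.5) -> None:
    """Resolve overlaps by damped Jacobi repulsion of equivalent circles,
    keeping attached buds glued to their mothers. Displacements are
    accumulated per sweep and capped per cell, which keeps dense packings
    stable (no cell is ever ejected by a cascade of pushes)."""
    n = len(cells)
    if n < 2:
        return
    by_label = {c.label: c for c in cells}
    index = {c.label: i for i, c in enumerate(cells)}
    C = np.array([c.center for c in cells])
    r = np.array([c.radius() for c in cells])
    area = np.array([c.area for c in cells])
    target = r[:, None] + r[None, :] - 0.8
    # attached buds are glued to their mothers below; excluding those pairs
    # from repulsion avoids a feedback loop (repulsion pushes the mother,
    # the glue drags the bud after her, and the pair self-propels)
    attached_pairs = []
    for c in cells:
        if c.attached_to is not None and c.attached_to in index:
            i, j = index[c.label], index[c.attached_to]
            target[i, j] = target[j, i] = 0.0
            attached_pairs.append((i, j))
    np.fill_diagonal(target, 0.0)
    w = area[None, :] / (area[:, None] + area[None, :])   # heavier moves less
    strength = 0.5 * cfg.crowding_push_strength
    overlap = np.inf
    for it in range(max_iter):
        delta = C[None, :, :] - C[:, None, :]             # i -> j
        d = np.sqrt((delta ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        pen = target - d
        overlap = float(pen.max())
        if overlap < 0.3:
            break
        active = pen > 0
        u = delta / d[..., None]
        push = np.where(active, pen, 0.0) * strength * w
        disp = -(u * push[..., None]).sum(axis=1)
        norms = np.sqrt((disp ** 2).sum(-1))
        scale = np.where(norms > max_step, max_step / np.maximum(norms, 1e-12),
                         1.0)
        C += disp * scale[:, None]
        # re-glue attached buds at touching distance from their mothers
        for i, j in attached_pairs:
            mother = cells[j]
            dvec = C[i] - C[j]
            dist = float(np.hypot(*dvec))
            if dist < 1e-9:
                continue
            phi = float(np.arctan2(dvec[0], dvec[1]))
            mother.center = C[j]      # boundary_radius uses current center
            want = mother.boundary_radius(phi) + np.sqrt(area[i] / np.pi) - 1.5
            C[i] = C[j] + dvec * (want / dist)
    for c, pos in zip(cells, C):
        c.center = pos
    if overlap > 3.0:
        raise SimulationError("could not resolve cell overlaps "
                              "(parameters too crowded)")


def _recenter(cfg: ColonyConfig, cells: list[_Cell]) -> None:
    centroid = np.mean([c.center for c in cells], axis=0)
    shift = np.array([cfg.canvas / 2.0, cfg.canvas / 2.0]) - centroid
    for c in cells:
        c.center += shift
    # hard bound: colony must fit the canvas
    for c in cells:
        a, _ = c.semiaxes()
        if (c.center - a < 2).any() or (c.center + a > cfg.canvas - 2).any():
            raise SimulationError("colony outgrew the canvas; increase "
                                  "`canvas` or reduce n_frames")


def _rasterize_ellipses(cfg: ColonyConfig, cells: list[_Cell]) -> np.ndarray:
    n = cfg.canvas
    labels = np.zeros((n, n), dtype=np.int32)
    best = np.full((n, n), np.inf)
    for c in cells:
        a, b = c.semiaxes()
        u = np.array([np.sin(c.theta), np.cos(c.theta)])    # major axis dir
        v = np.array([-u[1], u[0]])
        r0 = max(int(c.center[0] - a - 2), 0)
        r1 = min(int(c.center[0] + a + 3), n)
        c0 = max(int(c.center[1] - a - 2), 0)
        c1 = min(int(c.center[1] + a + 3), n)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        dr = rr - c.center[0]
        dc = cc - c.center[1]
        q = ((dr * u[0] + dc * u[1]) / a) ** 2 \
            + ((dr * v[0] + dc * v[1]) / b) ** 2
        sel = (q <= 1.0) & (q < best[r0:r1, c0:c1])
        labels[r0:r1, c0:c1][sel] = c.label
        best[r0:r1, c0:c1][sel] = q[sel]
    return _largest_components(labels)


def _largest_components(labels: np.ndarray) -> np.ndarray:
    """Keep only the largest 4-connected component of each label (stray
    pixels from contested rasterization go to background)."""
    from scipy import ndimage
    out = labels.copy()
    for lab in np.unique(labels):
        if lab == 0:
            continue
        mask = labels == lab
        comp, n = ndimage.label(mask)
        if n > 1:
            sizes = ndimage.sum_labels(np.ones_like(comp), comp,
                                       index=np.arange(1, n + 1))
            keep = 1 + int(np.argmax(sizes))
            out[mask & (comp != keep)] = 0
    return out


def _render_fluo(cfg: ColonyConfig, rng, cells: list[_Cell],
                 junctions: dict[int, tuple[int, int]], t: int) -> np.ndarray:
    n = cfg.canvas
    img = rng.normal(200.0, 20.0, (n, n))
    by_label = {c.label: c for c in cells}
    for bud_label, (mother_label, birth) in junctions.items():
        if not (birth <= t < birth + cfg.spot_frames):
            continue
        bud = by_label.get(bud_label)
        mother = by_label.get(mother_label)
        if bud is None or mother is None:
            continue
        delta = bud.center - mother.center
        phi = float(np.arctan2(delta[0], delta[1]))
        jpt = mother.center + mother.boundary_radius(phi) \
            * np.array([np.sin(phi), np.cos(phi)])
        _add_spot(img, jpt, cfg.spot_intensity, cfg.spot_sigma)
    return np.clip(img, 0, 65535).astype(np.uint16)


def _add_spot(img: np.ndarray, center: np.ndarray,
              amplitude: float, sigma: float) -> None:
    n = img.shape[0]
    half = int(np.ceil(4 * sigma))
    r0 = max(int(center[0]) - half, 0)
    r1 = min(int(center[0]) + half + 1, n)
    c0 = max(int(center[1]) - half, 0)
    c1 = min(int(center[1]) + half + 1, n)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    img[r0:r1, c0:c1] += amplitude * np.exp(
        -((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma ** 2))


def _fold(theta: float) -> float:
    return float((theta + np.pi / 2) % np.pi - np.pi / 2)


# ---------------------------------------------------------------------------
# fission mode
# ---------------------------------------------------------------------------

def _simulate_fission(cfg: ColonyConfig, rng) -> SyntheticGroundTruth:
    cells: list[_Cell] = []
    c0 = cfg.canvas / 2.0
    next_label = 1
    w = cfg.fission_width
    for _ in range(cfg.initial_cells):
        L = float(rng.uniform(1.2, 1.8) * 2.2 * w)
        cells.append(_make_rod(cfg, rng, next_label,
                               np.array([c0, c0])
                               + rng.normal(0, 8.0 * cfg.initial_cells, 2),
                               L, birth=0))
        next_label += 1

    frames, lineage_rows, tracklets = [], [], []
    for t in range(cfg.n_frames):
        if t > 0 and not cfg.frozen:
            g = 2.0 ** (1.0 / cfg.mean_cell_cycle_frames)
            for c in cells:
                c.length *= g * float(np.exp(rng.normal(0, 0.01)))
                c.theta = _fold(c.theta + rng.normal(0, 0.015))
                c.area = _rod_area(c.length, c.width)
            divided: list[_Cell] = []
            survivors: list[_Cell] = []
            for c in cells:
                if c.length >= c.countdown:      # countdown = division length
                    u = np.array([np.sin(c.theta), np.cos(c.theta)])
                    Lh = (c.length - 1.0) / 2.0
                    for sgn in (+1.0, -1.0):
                        d = _make_rod(cfg, rng, next_label,
                                      c.center + sgn * u * (c.length / 4.0),
                                      Lh, birth=t, theta=c.theta)
                        lineage_rows.append((d.label, c.label, t))
                        divided.append(d)
                        next_label += 1
                else:
                    survivors.append(c)
            cells = survivors + divided
        if not (cfg.frozen and t > 0):
            _relax_fission(cfg, cells)
            _recenter(cfg, cells)
        frames.append(LabeledFrame(index=t, labels=_rasterize_rods(cfg, cells)))
        if t > 0:
            prev = frames[-2].cell_ids
            cur = frames[-1].cell_ids
            tracklets.append({lab: lab for lab in prev & cur})

    movie = MaskMovie(frames, frame_interval_minutes=cfg.frame_interval_minutes)
    return SyntheticGroundTruth(movie=movie, lineage=LineageTable(lineage_rows),
                                tracklets=tracklets, config=cfg)


def _make_rod(cfg: ColonyConfig, rng, label: int, center: np.ndarray,
              length: float, birth: int, theta: float | None = None) -> _Cell:
    w = float(rng.normal(cfg.fission_width, 0.4))
    if theta is None:
        theta = float(rng.uniform(-np.pi / 2, np.pi / 2))
    else:
        theta = _fold(theta + rng.normal(0, 0.05))
    div_len = float(max(2.2 * w,
                        rng.normal(2.0, cfg.growth_rate_cv) * length * 2.0))
    # division length ~ double the birth length, with noise
    div_len = float(rng.normal(2.0 * length, cfg.growth_rate_cv * length))
    div_len = max(div_len, length * 1.4)
    return _Cell(label=label, center=center.astype(float),
                 area=_rod_area(length, w), theta=theta, aspect=1.0,
                 mature_area=0.0, cycle=0.0, countdown=div_len,
                 birth_frame=birth, length=float(length), width=w)


def _rod_area(L: float, w: float) -> float:
    return float(w * max(L - w, 0.0) + np.pi * (w / 2.0) ** 2)


def _rod_segment(c: _Cell) -> tuple[np.ndarray, np.ndarray]:
    u = np.array([np.sin(c.theta), np.cos(c.theta)])
    h = max(c.length - c.width, 0.0) / 2.0
    return c.center - h * u, c.center + h * u


def _segment_distance(p1, p2, q1, q2) -> tuple[float, np.ndarray, np.ndarray]:
    """Closest distance between segments and the closest points."""
    # sample-based: robust and plenty accurate for packing purposes
    ts = np.linspace(0.0, 1.0, 9)
    P = p1[None] + ts[:, None] * (p2 - p1)[None]
    Q = q1[None] + ts[:, None] * (q2 - q1)[None]
    d2 = ((P[:, None, :] - Q[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(np.argmin(d2), d2.shape)
    return float(np.sqrt(d2[i, j])), P[i], Q[j]


def _relax_fission(cfg: ColonyConfig, cells: list[_Cell],
                   max_iter: int = 400, max_step: float = 1.5,
                   n_samples: int = 7) -> None:
    """Damped Jacobi repulsion for capsules: each rod is sampled along its
    axis segment and the closest sample pair drives the push."""
    n = len(cells)
    if n < 2:
        return
    widths = np.array([c.width for c in cells])
    target = (widths[:, None] + widths[None, :]) / 2.0 - 0.8
    np.fill_diagonal(target, 0.0)
    ts = np.linspace(0.0, 1.0, n_samples)
    strength = 0.5 * cfg.crowding_push_strength
    C = np.array([c.center for c in cells])
    overlap = np.inf
    for it in range(max_iter):
        P = np.empty((n, n_samples, 2))
        for i, c in enumerate(cells):
            c.center = C[i]
            p1, p2 = _rod_segment(c)
            P[i] = p1[None] + ts[:, None] * (p2 - p1)[None]
        # pairwise min distance over sample points
        diff = P[:, None, :, None, :] - P[None, :, None, :, :]
        d2 = (diff ** 2).sum(-1)                     # (n, n, s, s)
        dmin = np.sqrt(d2.min(axis=(2, 3)))
        np.fill_diagonal(dmin, np.inf)
        pen = target - dmin
        overlap = float(pen.max())
        if overlap < 0.3:
            break
        flat = d2.reshape(n, n, -1)
        amin = flat.argmin(axis=2)
        ai, bi = np.unravel_index(amin, (n_samples, n_samples))
        rows = np.arange(n)
        Pa = P[rows[:, None], ai]                    # closest point on rod i
        Pb = P[np.broadcast_to(rows[None, :], (n, n)), bi]  # ... on rod j
        u = Pb - Pa
        nu = np.sqrt((u ** 2).sum(-1, keepdims=True))
        u = np.where(nu > 1e-9, u / np.maximum(nu, 1e-12),
                     np.array([0.0, 1.0]))
        push = np.where(pen > 0, pen, 0.0) * strength * 0.5
        disp = -(u * push[..., None]).sum(axis=1)
        norms = np.sqrt((disp ** 2).sum(-1))
        scale = np.where(norms > max_step, max_step / np.maximum(norms, 1e-12),
                         1.0)
        C += disp * scale[:, None]
    for c, pos in zip(cells, C):
        c.center = pos
    if overlap > 3.0:
        raise SimulationError("could not resolve rod overlaps")


def _rasterize_rods(cfg: ColonyConfig, cells: list[_Cell]) -> np.ndarray:
    n = cfg.canvas
    labels = np.zeros((n, n), dtype=np.int32)
    best = np.full((n, n), np.inf)
    for c in cells:
        p1, p2 = _rod_segment(c)
        half = c.width / 2.0
        r0 = max(int(min(p1[0], p2[0]) - half - 2), 0)
        r1 = min(int(max(p1[0], p2[0]) + half + 3), n)
        c0 = max(int(min(p1[1], p2[1]) - half - 2), 0)
        c1 = min(int(max(p1[1], p2[1]) + half + 3), n)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        pts = np.stack([rr, cc], axis=-1).astype(float)
        seg = p2 - p1
        L2 = float(seg @ seg)
        if L2 < 1e-12:
            t = np.zeros(pts.shape[:2])
        else:
            t = np.clip(((pts - p1) @ seg) / L2, 0.0, 1.0)
        closest = p1 + t[..., None] * seg
        dist = np.sqrt(((pts - closest) ** 2).sum(-1))
        q = dist / half
        sel = (q <= 1.0) & (q < best[r0:r1, c0:c1])
        labels[r0:r1, c0:c1][sel] = c.label
        best[r0:r1, c0:c1][sel] = q[sel]
    return _largest_components(labels)


# ---------------------------------------------------------------------------
# subsampling
# ---------------------------------------------------------------------------

def subsample(gt: SyntheticGroundTruth, stride: int) -> SyntheticGroundTruth:
    """Keep every ``stride``-th frame, composing ground-truth tracklets
    transitively and re-indexing the lineage table.

    Emulates recording at longer frame intervals, which makes tracking
    progressively harder.
    """
    n = len(gt.movie)
    if stride < 1 or stride >= n:
        raise ValueError(f"stride {stride} invalid for {n} frames")
    kept = list(range(0, n, stride))
    frames = [LabeledFrame(index=i, labels=gt.movie[k].labels.copy())
              for i, k in enumerate(kept)]
    movie = MaskMovie(frames,
                      frame_interval_minutes=(gt.movie.frame_interval_minutes
                                              * stride),
                      scale_factor=gt.movie.scale_factor)
    tracklets = []
    for a, b in zip(kept[:-1], kept[1:]):
        ids_a = gt.movie[a].cell_ids
        ids_b = gt.movie[b].cell_ids
        # labels are globally consistent, so composition = set intersection
        tracklets.append({lab: lab for lab in ids_a & ids_b})
    rows = []
    for row in gt.lineage:
        # first retained frame at or after the original budding frame
        new_frame = int(np.ceil(row.budding_frame / stride))
        if new_frame < len(kept):
            rows.append((row.bud_id, row.mother_id, new_frame))
    fluo = gt.fluorescence[kept] if gt.fluorescence is not None else None
    return SyntheticGroundTruth(movie=movie, lineage=LineageTable(rows),
                                tracklets=tracklets, fluorescence=fluo,
                                config=gt.config)
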