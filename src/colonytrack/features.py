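"""Geometric features of single cells and within-frame cell pairs.

All features are computed from label masks alone — never from the
underlying microscopy images — so the tracker is insensitive to imaging
conditions. Single-cell descriptors come from a PCA of the cell's pixel
coordinates (equivalent-ellipse convention: full axis length = 4·sqrt of
the corresponding eigenvalue); pair descriptors encode relative position
of two cells in the same frame, including the closest distance between
their contours ("closest points along their contours": sub-pixel
``find_contours`` polylines at level 0.5, so that 8-connected touching
cells have distance exactly 0).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure

from .mask_io import LabeledFrame

__all__ = [
    "SingleCellFeatures",
    "PairFeatures",
    "CellRecord",
    "FrameGeometry",
    "extract_cell",
    "pair_features",
    "fourier_descriptors",
    "CELL_VECTOR_NAMES",
    "PAIR_VECTOR_NAMES",
    "PAIR_VECTOR_FLIP",
]

#: Distance below which two sub-pixel contours are considered touching
#: (covers exact shared edges and 8-connected diagonal contact).
_TOUCH_EPS = 0.75


@dataclasses.dataclass
class SingleCellFeatures:
    area: float
    major_axis: float
    minor_axis: float
    geom_mean_axes: float
    orientation: float      # radians, axial, in [-pi/2, pi/2)
    eccentricity: float
    fourier: np.ndarray | None = None

    def vector(self) -> np.ndarray:
        """Numeric encoding used by the tracking network.

        The axial orientation angle is encoded as (cos 2θ, sin 2θ) so that
        θ and θ+π (the same undirected axis) map to the same point and the
        ±π/2 wrap has no discontinuity.
        """
        return np.array([
            self.area, self.major_axis, self.minor_axis,
            self.geom_mean_axes, self.eccentricity,
            np.cos(2.0 * self.orientation), np.sin(2.0 * self.orientation),
        ])


CELL_VECTOR_NAMES = [
    "area", "major_axis", "minor_axis", "geom_mean_axes",
    "eccentricity", "cos2_orientation", "sin2_orientation",
]


@dataclasses.dataclass
class PairFeatures:
    dx: float                # CoM-to-CoM column offset (b - a)
    dy: float                # CoM-to-CoM row offset (b - a)
    length: float            # Euclidean CoM distance
    angle: float             # directed, radians in (-pi, pi]
    closest_distance: float  # min contour-to-contour distance, 0 if touching

    def vector(self) -> np.ndarray:
        return np.array([
            self.dx, self.dy, self.length,
            np.cos(self.angle), np.sin(self.angle),
            self.closest_distance,
        ])


PAIR_VECTOR_NAMES = ["dx", "dy", "length", "cos_angle", "sin_angle",
                     "closest_distance"]
#: Sign flips that turn the a->b pair vector into the b->a pair vector.
PAIR_VECTOR_FLIP = np.array([-1.0, -1.0, 1.0, -1.0, -1.0, 1.0])


@dataclasses.dataclass
class CellRecord:
    label: int
    com: tuple[float, float]          # (row, col)
    contour: np.ndarray               # (M, 2) float (row, col), closed outer boundary
    features: SingleCellFeatures
    n_pixels: int


class MissingCellError(KeyError):
    pass


def _fold_axial(theta: float) -> float:
    """Fold an angle into [-pi/2, pi/2) (a principal axis is undirected)."""
    theta = (theta + np.pi / 2) % np.pi - np.pi / 2
    if theta >= np.pi / 2:       # numerical edge
        theta -= np.pi
    return float(theta)


def extract_cell(labels: np.ndarray, label: int,
                 with_fourier: bool = False) -> CellRecord:
    """Extract the geometric record of one labeled cell.

    PCA of the pixel coordinates gives eigenvalues λ1 ≥ λ2; the full axis
    lengths are 4·sqrt(λ) (equivalent ellipse). Orientation is the angle
    of the major eigenvector to the column axis, folded into [-pi/2, pi/2).
    One-pixel cells are handled as degenerate, with both axes floored at
    1 px and zero eccentricity.
    """
    labels = np.asarray(labels)
    coords = np.argwhere(labels == label)
    if coords.size == 0:
        raise MissingCellError(f"label {label} not present")
    n = len(coords)
    com = coords.mean(axis=0)

    if n == 1:
        major = minor = 1.0
        orientation = 0.0
        ecc = 0.0
    else:
        cov = np.cov(coords.T, bias=True)
        evals, evecs = np.linalg.eigh(cov)       # ascending
        lam2, lam1 = float(evals[0]), float(evals[1])
        v1 = evecs[:, 1]                         # (row, col) of major axis
        major = max(4.0 * np.sqrt(max(lam1, 0.0)), 1.0)
        minor = max(4.0 * np.sqrt(max(lam2, 0.0)), 1.0)
        orientation = _fold_axial(np.arctan2(v1[0], v1[1]))
        ecc = float(np.sqrt(max(0.0, 1.0 - (minor / major) ** 2)))

    contour = _outer_contour(labels, label, coords)
    feats = SingleCellFeatures(
        area=float(n), major_axis=float(major), minor_axis=float(minor),
        geom_mean_axes=float(np.sqrt(major * minor)),
        orientation=orientation, eccentricity=ecc,
    )
    if with_fourier:
        feats.fourier = fourier_descriptors(contour)
    return CellRecord(label=int(label), com=(float(com[0]), float(com[1])),
                      contour=contour, features=feats, n_pixels=n)


def _outer_contour(labels: np.ndarray, label: int,
                   coords: np.ndarray) -> np.ndarray:
    """Closed sub-pixel outer boundary of the cell (largest component if
    the label is fragmented; fragmentation is a warning, not an error)."""
    r0, c0 = coords.min(axis=0)
    r1, c1 = coords.max(axis=0)
    mask = (labels[r0:r1 + 1, c0:c1 + 1] == label)
    padded = np.pad(mask, 1).astype(float)
    contours = measure.find_contours(padded, 0.5, fully_connected="high")
    if len(contours) > 1:
        lengths = [len(c) for c in contours]
        if mask.sum() > 1:
            n_comp = measure.label(mask, connectivity=2).max()
            if n_comp > 1:
                warnings.warn(f"label {label} is fragmented into "
                              f"{n_comp} components; using largest")
        contour = contours[int(np.argmax(lengths))]
    else:
        contour = contours[0]
    # drop the repeated closing vertex, undo the padding offset
    contour = contour[:-1] + np.array([r0 - 1, c0 - 1])
    return contour


def pair_features(a: CellRecord, b: CellRecord) -> PairFeatures:
    """Relative-position features of two cells from the same frame."""
    if a.label == b.label and a is b:
        return PairFeatures(0.0, 0.0, 0.0, 0.0, 0.0)
    dy = b.com[0] - a.com[0]
    dx = b.com[1] - a.com[1]
    length = float(np.hypot(dx, dy))
    angle = float(np.arctan2(dy, dx))
    if angle <= -np.pi:
        angle += 2.0 * np.pi
    d = closest_contour_distance(a.contour, b.contour)
    return PairFeatures(float(dx), float(dy), length, angle, d)


def closest_contour_distance(contour_a: np.ndarray,
                             contour_b: np.ndarray) -> float:
    """Minimum Euclidean distance between two contour polylines' vertices;
    snapped to 0 below the touching threshold (shared edges or 8-connected
    diagonal contact)."""
    tree = cKDTree(contour_b)
    d = float(tree.query(contour_a, k=1)[0].min())
    return 0.0 if d < _TOUCH_EPS else d


def fourier_descriptors(contour: np.ndarray, k: int = 10) -> np.ndarray:
    """Magnitudes of the first ``k`` non-DC Fourier coefficients of the
    complex contour signal col + i·row, normalized by the first magnitude.

    Translation affects only the DC term, rotation only phases, and scale
    cancels in the normalization, so the descriptors are invariant to all
    three. Off by default in the tracking feature vector (they were not
    found to help tracking).
    """
    contour = np.asarray(contour, dtype=float)
    if len(contour) < k + 1:
        raise ValueError(f"contour with {len(contour)} points is too short "
                         f"for {k} descriptors")
    z = contour[:, 1] + 1j * contour[:, 0]
    F = np.fft.fft(z)
    mags = np.abs(F[1:k + 1])
    return mags / mags[0]


#: Version tag of the per-cell feature CSV layout below.
FEATURE_SCHEMA_VERSION = "cell-features-v1"


def features_table(geos: "list[FrameGeometry]"):
    """Headered per-cell feature table (one row per cell per frame) for
    inspection/export; column order is fixed by the schema version."""
    import pandas as pd
    rows = []
    for geo in geos:
        for lab in geo.labels_sorted:
            rec = geo.record(lab)
            rows.append([geo.frame.index, lab, rec.com[0], rec.com[1],
                         *rec.features.vector()])
    return pd.DataFrame(
        rows, columns=["frame", "label", "com_row", "com_col",
                       *CELL_VECTOR_NAMES])


class FrameGeometry:
    """Per-frame cache of cell records, contour KD-trees, and pairwise
    closest-contour distances (each pair computed once)."""

    def __init__(self, frame: LabeledFrame, with_fourier: bool = False):
        self.frame = frame
        self.labels_sorted = sorted(frame.cell_ids)
        self.records: dict[int, CellRecord] = {
            lab: extract_cell(frame.labels, lab, with_fourier=with_fourier)
            for lab in self.labels_sorted
        }
        self._trees: dict[int, cKDTree] = {}
        self._dist_cache: dict[tuple[int, int], float] = {}
        # circumradius: max distance from CoM to the contour, used for
        # conservative pruning bounds on contour-to-contour distances
        self._rmax: dict[int, float] = {
            lab: float(np.sqrt(((rec.contour - np.asarray(rec.com)) ** 2)
                               .sum(axis=1).max()))
            for lab, rec in self.records.items()}
        self.coms = np.array([self.records[lab].com
                              for lab in self.labels_sorted]) \
            if self.labels_sorted else np.zeros((0, 2))

    def __len__(self) -> int:
        return len(self.labels_sorted)

    def record(self, label: int) -> CellRecord:
        try:
            return self.records[label]
        except KeyError:
            raise MissingCellError(f"label {label} not in frame "
                                   f"{self.frame.index}") from None

    def tree(self, label: int) -> cKDTree:
        t = self._trees.get(label)
        if t is None:
            t = cKDTree(self.record(label).contour)
            self._trees[label] = t
        return t

    def closest_distance(self, a: int, b: int) -> float:
        """Closest contour-to-contour distance between cells ``a`` and ``b``."""
        if a == b:
            return 0.0
        key = (a, b) if a < b else (b, a)
        d = self._dist_cache.get(key)
        if d is None:
            d = float(self.tree(b).query(self.record(a).contour, k=1)[0].min())
            d = 0.0 if d < _TOUCH_EPS else d
            self._dist_cache[key] = d
        return d

    def pair(self, a: int, b: int) -> PairFeatures:
        ra, rb = self.record(a), self.record(b)
        dy = rb.com[0] - ra.com[0]
        dx = rb.com[1] - ra.com[1]
        length = float(np.hypot(dx, dy))
        angle = float(np.arctan2(dy, dx))
        if angle <= -np.pi:
            angle += 2.0 * np.pi
        return PairFeatures(float(dx), float(dy), length, angle,
                            self.closest_distance(a, b))

    def relabeled(self, mapping: dict[int, int],
                  labels_img: np.ndarray) -> "FrameGeometry":
        """A view of this geometry under a label renaming (no recompute).

        ``labels_img`` is the already-relabeled label image; geometry is
        label-independent, so records, trees and cached distances are
        simply re-keyed."""
        new = object.__new__(FrameGeometry)
        new.frame = LabeledFrame(self.frame.index, labels_img)
        new.labels_sorted = sorted(mapping[l] for l in self.labels_sorted)
        new.records = {}
        for old, rec in self.records.items():
            r = dataclasses.replace(rec, label=mapping[old])
            new.records[mapping[old]] = r
        new._trees = {mapping[old]: t for old, t in self._trees.items()}
        new._rmax = {mapping[old]: r for old, r in self._rmax.items()}
        new._dist_cache = {}
        for (a, b), d in self._dist_cache.items():
            a2, b2 = mapping[a], mapping[b]
            key = (a2, b2) if a2 < b2 else (b2, a2)
            new._dist_cache[key] = d
        new.coms = np.array([new.records[lab].com
                             for lab in new.labels_sorted]) \
            if new.labels_sorted else np.zeros((0, 2))
        return new

    def neighbors_within(self, label: int, max_dist: float) -> list[int]:
        """Labels of other cells whose closest contour distance to ``label``
        is <= max_dist, pre-gated by CoM distance for speed."""
        rec = self.record(label)
        out = []
        # contour distance >= CoM distance - (circumradius_a + _b)
        for other in self.labels_sorted:
            if other == label:
                continue
            ro = self.records[other]
            com_d = np.hypot(ro.com[0] - rec.com[0], ro.com[1] - rec.com[1])
            if com_d - self._rmax[label] - self._rmax[other] > max_dist:
                continue
            if self.closest_distance(label, other) <= max_dist:
                out.append(other)
        return out
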