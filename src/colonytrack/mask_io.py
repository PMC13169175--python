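"""Labeled-mask movie I/O and global area normalization.

The tracker consumes time-ordered stacks of 2-D integer label images
(0 = background, positive integers = cell IDs), one frame per timepoint,
either as a multi-page TIFF or as a directory of per-frame ``t{index:04d}``
image files. An optional co-registered 16-bit fluorescence channel is
carried as a parallel grayscale stack. Ground-truth lineage annotations
travel as a headered CSV with columns ``bud_id,mother_id,budding_frame``.

Before feature extraction, all frames of a movie are rescaled by one
common factor so that the mean cell area over the whole movie hits a
fixed target. This makes the downstream networks robust to microscope
magnification and zoom without needing acquisition metadata.
"""

from __future__ import annotations

import dataclasses
import pathlib
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "LabeledFrame",
    "MaskMovie",
    "LineageTable",
    "read_movie",
    "write_movie",
    "read_fluorescence",
    "write_fluorescence",
    "normalize_scale",
    "DEFAULT_TARGET_MEAN_AREA",
]

#: Default target mean cell area, px^2 (a ~28 px diameter yeast cell at 60x).
DEFAULT_TARGET_MEAN_AREA = 625.0


@dataclasses.dataclass
class LabeledFrame:
    """One timepoint: an integer label image plus its frame index."""

    index: int
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError("label image must have an integer dtype")

    @property
    def cell_ids(self) -> set[int]:
        ids = np.unique(self.labels)
        return set(int(v) for v in ids if v > 0)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclasses.dataclass
class MaskMovie:
    """Ordered sequence of :class:`LabeledFrame` sharing one canvas size.

    In tracked (ground-truth or tracker-output) movies, a label value reused
    across frames denotes the same cell.
    """

    frames: list[LabeledFrame]
    frame_interval_minutes: float = 5.0
    scale_factor: float = 1.0

    def __post_init__(self):
        if self.frames:
            shape = self.frames[0].labels.shape
            for f in self.frames:
                if f.labels.shape != shape:
                    raise ValueError(
                        f"frame {f.index} has shape {f.labels.shape}, "
                        f"expected {shape}")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> LabeledFrame:
        return self.frames[i]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].labels.shape

    def stack(self) -> np.ndarray:
        return np.stack([f.labels for f in self.frames])


class LineageTable:
    """Mother->bud table: rows of (bud_id, mother_id, budding_frame)."""

    COLUMNS = ["bud_id", "mother_id", "budding_frame"]

    def __init__(self, rows: Iterable[tuple[int, int, int]] = ()):
        self.df = pd.DataFrame(list(rows), columns=self.COLUMNS, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return iter(self.df.itertuples(index=False))

    def mother_of(self, bud_id: int) -> int:
        sel = self.df[self.df.bud_id == bud_id]
        if sel.empty:
            raise KeyError(f"bud {bud_id} not in lineage table")
        return int(sel.mother_id.iloc[0])

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LineageTable":
        df = pd.read_csv(path)
        missing = set(cls.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"lineage CSV missing columns: {sorted(missing)}")
        t = cls()
        t.df = df[cls.COLUMNS].astype(np.int64)
        return t


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _check_integer(arr: np.ndarray, where: str) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.integer):
        return arr
    if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.round(arr)):
        return arr.astype(np.int32)
    raise TypeError(f"non-integer pixel values in {where}")


def read_movie(path, frame_interval_minutes: float = 5.0) -> MaskMovie:
    """Read a labeled mask movie from a multi-page TIFF or a frame directory.

    A directory is expected to contain files named ``t0000.tif`` /
    ``t0000.png`` etc.; frames are ordered by the embedded index.
    """
    path = pathlib.Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.stem.startswith("t") and p.stem[1:].isdigit())
        if not files:
            raise FileNotFoundError(f"no t####.* frame files in {path}")
        pages = []
        for p in files:
            if p.suffix.lower() in (".tif", ".tiff"):
                pages.append(tifffile.imread(p))
            else:
                from imageio.v3 import imread
                pages.append(imread(p))
    else:
        if not path.exists():
            raise FileNotFoundError(path)
        pages = list(tifffile.imread(path))
    frames = []
    for i, page in enumerate(pages):
        arr = _check_integer(np.asarray(page), f"frame {i}")
        frames.append(LabeledFrame(index=i, labels=arr))
    return MaskMovie(frames, frame_interval_minutes=frame_interval_minutes)


def write_movie(movie: MaskMovie, path) -> None:
    """Write a movie as a multi-page TIFF (one page per frame)."""
    path = pathlib.Path(path)
    stack = movie.stack()
    # choose the narrowest dtype that holds every label
    maxlab = int(stack.max(initial=0))
    dtype = np.uint16 if maxlab < 2 ** 16 else np.uint32
    tifffile.imwrite(path, stack.astype(dtype), photometric="minisblack")


def read_fluorescence(path) -> np.ndarray:
    """Read a co-registered fluorescence stack (frames, H, W)."""
    arr = np.asarray(tifffile.imread(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_fluorescence(stack: np.ndarray, path) -> None:
    tifffile.imwrite(pathlib.Path(path), np.asarray(stack).astype(np.uint16),
                     photometric="minisblack")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def mean_cell_area(movie: MaskMovie) -> float:
    """Mean cell area (px^2) over every cell instance of every frame."""
    total_px = 0
    total_cells = 0
    for f in movie.frames:
        total_px += int(np.count_nonzero(f.labels))
        total_cells += f.n_cells
    if total_cells == 0:
        raise ValueError("movie contains no cells")
    return total_px / total_cells


def normalize_scale(movie: MaskMovie,
                    target_mean_area: float = DEFAULT_TARGET_MEAN_AREA,
                    ) -> MaskMovie:
    """Rescale all frames by one common factor so the movie-wide mean cell
    area equals ``target_mean_area``.

    The factor is s = sqrt(target / observed); label images are resampled
    with nearest-neighbor interpolation (anything smoother would corrupt
    labels). One global factor per movie, not per frame, so that growth
    dynamics within the movie are preserved.
    """
    observed = mean_cell_area(movie)
    s = float(np.sqrt(target_mean_area / observed))
    if abs(s - 1.0) < 1e-12:
        return MaskMovie([LabeledFrame(f.index, f.labels.copy())
                          for f in movie.frames],
                         movie.frame_interval_minutes, movie.scale_factor)
    frames = []
    for f in movie.frames:
        scaled = ndimage.zoom(f.labels, s, order=0, mode="grid-constant",
                              grid_mode=True)
        frames.append(LabeledFrame(f.index, scaled))
    return MaskMovie(frames, movie.frame_interval_minutes,
                     scale_factor=movie.scale_factor * s)
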